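"""Reference collagen peptide-marker panels and the taxonomy they live in.

A marker panel is one reference specimen's row of nominal peptide masses,
organised in ten fixed slots (A, B, X1, C, X2, D, X3, F, G, X4). Slots are
opaque labels for homologous tryptic collagen peptides; a slot may be empty
(no marker determined for that taxon) or carry one or two masses — compressed
"slash" cells such as ``1816/32`` denote two tryptic variants (1816 and 1832).

The packaged panel file is a verbatim transcription of the published table of
markers determined from modern comparative skeletal material; printed cells
are preserved so the file round-trips byte-identically, while normalised
fields (subfamily spelling, giraffe's family) drive the taxonomy used for
classification.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

SLOT_LABELS: tuple[str, ...] = ("A", "B", "X1", "C", "X2", "D", "X3", "F", "G", "X4")
"""The ten marker slots, in printed order."""

MZ_MIN, MZ_MAX = 700.0, 3700.0
"""MALDI-TOF acquisition bounds (m/z) used throughout the package."""

RANKS = ("species", "tribe", "subfamily", "family", "root")

_PANEL_COLUMNS = ("specimen_code", "family", "subfamily", "tribe",
                  "species", "common_name") + SLOT_LABELS

# Printed-cell normalisations applied when building the taxonomy. The fixture
# keeps the printed strings; these fix a spelling variant and a family cell
# that contradicts the study's own phylogeny (giraffes are not bovids).
SUBFAMILY_SPELLING = {"Antelopinae": "Antilopinae"}
FAMILY_CORRECTIONS = {"Giraffa camelopardalis": "Giraffidae"}


class PanelError(ValueError):
    """Malformed panel file or invalid marker mass."""


@dataclass(eq=False)
class TaxonNode:
    """A node in the species -> tribe -> subfamily -> family -> root hierarchy."""

    name: str
    rank: str
    common_name: str = ""
    parent: "TaxonNode | None" = None
    corrected: bool = False  # set when a printed cell was overridden

    def ancestors(self) -> list["TaxonNode"]:
        """This node followed by its ancestors up to the root."""
        chain, node = [], self
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    def is_within(self, clade: "TaxonNode") -> bool:
        """True if *clade* is this node or one of its ancestors."""
        return any(n is clade for n in self.ancestors())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.name!r}, rank={self.rank!r})"


class Taxonomy:
    """Parent-pointer taxonomy supporting lowest-common-ancestor queries."""

    def __init__(self) -> None:
        self.root = TaxonNode("Animalia", "root")
        self._nodes: dict[tuple[str, str], TaxonNode] = {("root", "Animalia"): self.root}

    def node(self, rank: str, name: str) -> TaxonNode:
        return self._nodes[(rank, name)]

    def find(self, name: str) -> TaxonNode | None:
        """Look up a node by name at any rank (species first)."""
        for rank in RANKS:
            hit = self._nodes.get((rank, name))
            if hit is not None:
                return hit
        return None

    def add(self, rank: str, name: str, parent: TaxonNode,
            common_name: str = "", corrected: bool = False) -> TaxonNode:
        """Add (or return the existing) node, checking rank ordering."""
        key = (rank, name)
        existing = self._nodes.get(key)
        if existing is not None:
            if common_name and not existing.common_name:
                existing.common_name = common_name
            return existing
        if RANKS.index(rank) >= RANKS.index(parent.rank):
            raise PanelError(
                f"rank {rank!r} of {name!r} does not nest under {parent.rank!r}")
        node = TaxonNode(name, rank, common_name, parent, corrected)
        self._nodes[key] = node
        return node

    def species(self) -> list[TaxonNode]:
        return [n for (rank, _), n in self._nodes.items() if rank == "species"]

    def lineage(self, family: str, subfamily: str = "", tribe: str = "") -> TaxonNode:
        """Ensure family/subfamily/tribe nodes exist; return the deepest one."""
        node = self.add("family", family, self.root)
        if subfamily:
            node = self.add("subfamily", subfamily, node)
        if tribe:
            node = self.add("tribe", tribe, node)
        return node

    def to_newick(self) -> str:
        """Export as a Newick string with ranks carried in internal node labels."""
        from skbio import TreeNode  # deferred: heavy import

        built: dict[int, TreeNode] = {}

        def get(node: TaxonNode) -> TreeNode:
            key = id(node)
            if key not in built:
                built[key] = TreeNode(name=f"{node.name} [{node.rank}]")
                if node.parent is not None:
                    get(node.parent).append(built[key])
            return built[key]

        for sp in self.species():
            get(sp)
        return str(get(self.root))


def lca(taxa: Iterable[TaxonNode]) -> TaxonNode:
    """Deepest node that is an ancestor-or-self of every input taxon."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("lca() requires a non-empty set of taxa")
    common: list[TaxonNode] = taxa[0].ancestors()
    for taxon in taxa[1:]:
        mine = set(map(id, taxon.ancestors()))
        common = [n for n in common if id(n) in mine]
    if not common:
        raise ValueError("taxa do not share a taxonomy")
    return common[0]


def expand_slash(cell: str) -> tuple[float, ...]:
    """Expand a printed mass cell into its masses.

    ``"1832"`` -> (1832,); ``"1832/48"`` -> (1832, 1848): the part after the
    slash replaces the final digits of the printed prefix.
    """
    cell = cell.strip()
    if not cell:
        return ()
    if "/" not in cell:
        return (float(cell),)
    prefix, suffix = cell.split("/", 1)
    prefix, suffix = prefix.strip(), suffix.strip()
    if not suffix.isdigit() or len(suffix) >= len(prefix):
        raise PanelError(f"cannot expand slash cell {cell!r}")
    second = prefix[: len(prefix) - len(suffix)] + suffix
    return (float(prefix), float(second))


@dataclass
class MarkerPanel:
    """One reference taxon's slot -> masses mapping."""

    taxon: TaxonNode
    masses: dict[str, tuple[float, ...]]
    provenance: str = ""
    printed: dict[str, str] = field(default_factory=dict)  # raw row cells

    @property
    def defined_slots(self) -> tuple[str, ...]:
        return tuple(s for s in SLOT_LABELS if self.masses.get(s))

    def all_masses(self) -> list[float]:
        return [m for s in SLOT_LABELS for m in self.masses.get(s, ())]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MarkerPanel({self.taxon.name!r}, {len(self.defined_slots)} slots)"


def panel_distance(p1: MarkerPanel, p2: MarkerPanel) -> int:
    """Number of slots, non-empty in both panels, whose mass-sets differ."""
    return sum(
        1
        for s in SLOT_LABELS
        if p1.masses.get(s) and p2.masses.get(s)
        and set(p1.masses[s]) != set(p2.masses[s])
    )


class ReferencePanels(Sequence[MarkerPanel]):
    """The loaded panel collection plus the taxonomy it induces.

    Behaves as a sequence of :class:`MarkerPanel`; keeps the source file's
    comment lines so serialisation round-trips byte-identically.
    """

    def __init__(self, panels: list[MarkerPanel], taxonomy: Taxonomy,
                 comments: list[str]) -> None:
        self.panels = panels
        self.taxonomy = taxonomy
        self.comments = comments

    def __len__(self) -> int:
        return len(self.panels)

    def __getitem__(self, i):  # type: ignore[override]
        return self.panels[i]

    def __iter__(self) -> Iterator[MarkerPanel]:
        return iter(self.panels)

    def for_taxon(self, name: str) -> MarkerPanel:
        """Panel for a species (scientific or common name, case-insensitive)."""
        for p in self.panels:
            if name in (p.taxon.name, p.taxon.common_name) or \
                    name.lower() == p.taxon.common_name.lower():
                return p
        raise KeyError(f"no reference panel for taxon {name!r}")

    def write(self, path: str | Path) -> None:
        write_reference_panels(self, path)


def packaged_path(name: str) -> Path:
    """Path of a packaged data fixture."""
    return Path(importlib.resources.files("zoomsid").joinpath("data", name))


def _archaeological_nodes(tax: Taxonomy) -> None:
    # Taxa identified in the archaeological record from previously published
    # markers; they carry taxonomy nodes but no packaged panel.
    equidae = tax.add("family", "Equidae", tax.root)
    tax.add("species", "Equus quagga", equidae, common_name="zebra")
    tax.add("family", "Leporidae", tax.root, common_name="hares")
    mustelidae = tax.add("family", "Mustelidae", tax.root)
    tax.add("species", "Aonyx capensis", mustelidae, common_name="clawless otter")
    bovidae = tax.lineage("Bovidae", "Antilopinae", "Hippotragini")
    tax.add("species", "Hippotragus sp.", bovidae, common_name="roan and/or sable")


def load_reference_panels(path: str | Path = "packaged",
                          extend_archaeological: bool = True) -> ReferencePanels:
    """Load a tab-delimited marker-panel file.

    ``path="packaged"`` loads the fixture shipped with the package. Columns:
    specimen_code, family, subfamily, tribe, species, common_name, then the ten
    slot columns; empty cell = no marker; slash notation allowed. Returns a
    sequence of panels whose taxa are linked into a shared :class:`Taxonomy`.
    """
    if path == "packaged":
        path = packaged_path("reference_marker_panels.tsv")
    path = Path(path)

    tax = Taxonomy()
    panels: list[MarkerPanel] = []
    comments: list[str] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if line.startswith("#"):
            comments.append(line)
            continue
        cells = line.split("\t")
        if not header_seen:
            if tuple(cells) != _PANEL_COLUMNS:
                raise PanelError(f"{path.name}:{lineno}: unexpected header")
            header_seen = True
            continue
        if len(cells) != len(_PANEL_COLUMNS):
            raise PanelError(
                f"{path.name}:{lineno}: expected {len(_PANEL_COLUMNS)} columns, "
                f"got {len(cells)}")
        row = dict(zip(_PANEL_COLUMNS, cells))

        family = FAMILY_CORRECTIONS.get(row["species"], row["family"])
        corrected = family != row["family"]
        subfamily = SUBFAMILY_SPELLING.get(row["subfamily"], row["subfamily"])
        parent = tax.lineage(family, subfamily, row["tribe"])
        if corrected:
            parent.corrected = True
        species = tax.add("species", row["species"], parent,
                          common_name=row["common_name"])

        masses: dict[str, tuple[float, ...]] = {}
        for slot in SLOT_LABELS:
            try:
                expanded = expand_slash(row[slot])
            except ValueError as exc:
                raise PanelError(f"{path.name}:{lineno}: slot {slot}: {exc}") from exc
            for m in expanded:
                if not MZ_MIN <= m <= MZ_MAX:
                    raise PanelError(
                        f"{path.name}:{lineno}: slot {slot}: mass {m} outside "
                        f"[{MZ_MIN:g}, {MZ_MAX:g}]")
            if len(expanded) > 2:
                raise PanelError(f"{path.name}:{lineno}: slot {slot}: >2 masses")
            masses[slot] = expanded
        panels.append(MarkerPanel(species, masses,
                                  provenance=row["specimen_code"], printed=row))

    if extend_archaeological:
        _archaeological_nodes(tax)
    return ReferencePanels(panels, tax, comments)


def write_reference_panels(panels: ReferencePanels | Sequence[MarkerPanel],
                           path: str | Path) -> None:
    """Serialise panels back to the tab-delimited dialect.

    Printed cells are re-emitted verbatim where available, so a loaded file is
    reproduced byte-identically.
    """
    comments = getattr(panels, "comments", [])
    lines = list(comments)
    lines.append("\t".join(_PANEL_COLUMNS))
    for p in panels:
        if p.printed:
            lines.append("\t".join(p.printed[c] for c in _PANEL_COLUMNS))
        else:
            cells = [p.provenance, "", "", "", p.taxon.name, p.taxon.common_name]
            for slot in SLOT_LABELS:
                cells.append("/".join(f"{m:g}" for m in p.masses.get(slot, ())))
            lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
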