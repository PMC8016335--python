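"""Taxonomic assignment of peak lists against reference marker panels.

The matching rule formalises expert reading of a collagen fingerprint:

1. For every reference panel, a slot is *matched* when some peak lies within
   +/- tolerance of one of the slot's masses (nearest peak wins; a peak may
   support slots in several panels, but within one panel each slot is matched
   at most once).
2. Panels qualify as candidates when they reach ``min_matched`` matched slots
   and ``min_coverage`` of their defined slots.
3. With the *absence check* on, a qualifier is discarded when another
   qualifier matches all of its matched slots and additionally explains a
   spectrum peak the first panel cannot (within tolerance of none of its
   masses). This is how a shared-mass panel is separated from one carrying an
   extra diagnostic peak — e.g. a giraffe spectrum shows m/z 3003 and no 3033,
   and a warthog spectrum shows m/z 1848, which the red river hog panel lacks.
4. Candidates are the surviving qualifiers with the maximum matched-slot
   count; ambiguity is never broken arbitrarily — the result is the lowest
   common ancestor (LCA) of the candidates, which is why conserved bovid
   groups resolve only to tribe.

Deamidated collagen is common in degraded bone; an optional expansion also
tries each panel mass at +0.98 and +1.98 Da (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_panels import (MarkerPanel, ReferencePanels, SLOT_LABELS,
                               TaxonNode, lca)
from .spectra_io import PeakList

DEAMIDATION_SHIFTS = (0.0, 0.98402, 1.96804)  # 0, 1 and 2 deamidations


@dataclass(frozen=True)
class ClassifierParams:
    """Matching thresholds.

    tolerance
        Peak-to-marker window in Da; +/-0.5 Da suits the nominal integer
        masses of the packaged panels.
    min_matched, min_coverage
        Minimum matched slots (4) and fraction of defined slots (0.5) to call
        a positive — the three highly conserved collagen peptides (1427, 2131,
        2883) alone must never suffice.
    absence_check
        Enable candidate discrimination by unexplained diagnostic peaks.
    deamidation
        Also try panel masses shifted by +0.98/+1.98 Da.
    """

    tolerance: float = 0.5
    min_matched: int = 4
    min_coverage: float = 0.5
    absence_check: bool = True
    deamidation: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")


@dataclass
class SlotMatch:
    slot: str
    panel_mass: float
    observed_mz: float
    delta: float  # observed - panel mass (possibly deamidation-shifted)


@dataclass
class MatchResult:
    """Outcome of matching one peak list against one panel."""

    taxon: TaxonNode
    panel: MarkerPanel
    matched_slots: list[SlotMatch]
    missing_slots: list[str]
    explained: np.ndarray  # bool per spectrum peak: within tolerance of any panel mass

    @property
    def n_matched(self) -> int:
        return len(self.matched_slots)

    @property
    def coverage(self) -> float:
        defined = len(self.panel.defined_slots)
        return self.n_matched / defined if defined else 0.0


@dataclass
class Identification:
    """Classifier output for one specimen."""

    specimen_id: str
    status: str  # "identified" | "no_id"
    candidate_taxa: list[TaxonNode]
    resolved_clade: TaxonNode | None
    per_taxon: list[MatchResult]
    parameters: ClassifierParams

    @property
    def is_identified(self) -> bool:
        return self.status == "identified"


def _panel_mass_grid(panel: MarkerPanel, deamidation: bool) -> tuple[np.ndarray, ...]:
    shifts = DEAMIDATION_SHIFTS if deamidation else (0.0,)
    masses, slots = [], []
    for slot in SLOT_LABELS:
        for m in panel.masses.get(slot, ()):
            for s in shifts:
                masses.append(m + s)
                slots.append(slot)
    return np.asarray(masses), np.asarray(slots)


def _nearest_peaks(mz: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each target mass, index and distance of the nearest peak."""
    pos = np.searchsorted(mz, targets)
    left = np.clip(pos - 1, 0, mz.size - 1)
    right = np.clip(pos, 0, mz.size - 1)
    d_left = np.abs(mz[left] - targets)
    d_right = np.abs(mz[right] - targets)
    use_right = d_right < d_left
    idx = np.where(use_right, right, left)
    return idx, np.where(use_right, d_right, d_left)


def match_panel(pl: PeakList, panel: MarkerPanel, tolerance: float = 0.5,
                deamidation: bool = False) -> MatchResult:
    """Match a peak list against one panel (see module docstring, step 1)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    defined = panel.defined_slots
    if not len(pl) or not defined:
        return MatchResult(panel.taxon, panel, [], list(defined),
                           np.zeros(len(pl), dtype=bool))

    masses, slots = _panel_mass_grid(panel, deamidation)
    idx, dist = _nearest_peaks(pl.mz, masses)
    within = dist <= tolerance

    explained = np.zeros(len(pl), dtype=bool)
    explained[idx[within]] = True

    matched: dict[str, SlotMatch] = {}
    for i in np.flatnonzero(within):
        slot = str(slots[i])
        cand = SlotMatch(slot, float(masses[i]), float(pl.mz[idx[i]]),
                         float(pl.mz[idx[i]] - masses[i]))
        # one mass per slot: keep the closest pair
        if slot not in matched or abs(cand.delta) < abs(matched[slot].delta):
            matched[slot] = cand
    ordered = [matched[s] for s in SLOT_LABELS if s in matched]
    missing = [s for s in defined if s not in matched]
    return MatchResult(panel.taxon, panel, ordered, missing, explained)


def _apply_absence_check(qualifiers: list[MatchResult]) -> list[MatchResult]:
    """Drop qualifiers dominated by another qualifier with an unexplained peak."""
    keep = []
    for p in qualifiers:
        p_slots = {m.slot for m in p.matched_slots}
        dominated = False
        for q in qualifiers:
            if q is p:
                continue
            q_slots = {m.slot for m in q.matched_slots}
            if q_slots >= p_slots and bool(np.any(q.explained & ~p.explained)):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    return keep


def classify(pl: PeakList, panels: ReferencePanels | list[MarkerPanel],
             params: ClassifierParams | None = None) -> Identification:
    """Assign a peak list to the lowest unambiguous clade (module docstring)."""
    if params is None:
        params = ClassifierParams()
    panel_list = list(panels)
    if not panel_list:
        raise ValueError("classify() requires at least one reference panel")

    results = [match_panel(pl, p, params.tolerance, params.deamidation)
               for p in panel_list]
    qualifiers = [r for r in results
                  if r.n_matched >= params.min_matched
                  and r.coverage >= params.min_coverage]
    if params.absence_check:
        qualifiers = _apply_absence_check(qualifiers)

    if not qualifiers:
        return Identification(pl.specimen_id, "no_id", [], None, results, params)

    best = max(r.n_matched for r in qualifiers)
    candidates = [r.taxon for r in qualifiers if r.n_matched == best]
    return Identification(pl.specimen_id, "identified", candidates,
                          lca(candidates), results, params)


def identifiability_report(panels: ReferencePanels,
                           params: ClassifierParams | None = None):
    """Resolution attainable for each reference taxon from its own full panel.

    Feeds every panel's complete mass list (noise-free, both slash variants)
    back through :func:`classify` and reports the rank and name of the
    resolved clade. Conserved groups (e.g. the three Alcelaphini references)
    resolve only to tribe; taxa with private markers resolve to species.
    """
    import pandas as pd

    from .spectra_io import make_peaklist

    if params is None:
        params = ClassifierParams()
    rows = []
    for panel in panels:
        pl = make_peaklist(panel.all_masses(), specimen_id=panel.taxon.name)
        ident = classify(pl, panels, params)
        clade = ident.resolved_clade
        rows.append({
            "taxon": panel.taxon.name,
            "common_name": panel.taxon.common_name,
            "resolvable_rank": clade.rank if clade else "no_id",
            "resolved_clade": clade.name if clade else "",
            "n_candidates": len(ident.candidate_taxa),
        })
    return pd.DataFrame(rows)
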