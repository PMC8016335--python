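"""Selection-preference analytics over the packaged archaeological tables.

Four packaged fixtures transcribe the study's printed tables: the per-site
faunal MNI table, the bone-point sampling table, the per-site positive-rate
table, and the per-specimen identification table. The operations here
recompute the study's composition quantities from those transcriptions:
positive rates, tribe composition of the identified bone points, period
(pre-contact vs contact) breakdowns, tools made from animals absent in the
unmodified fauna, faunal tribe shares, sampling fractions, weighted positive
rates, and a permutation test of selection against the faunal background.

Printed-percentage reproductions use half-up rounding at the printed
precision. One documented exception: the source's own tables disagree on
KwaGandaganda (the positive-rate table says 6 positives of 11 sampled, while
the identification table lists 7 identified specimens among only 10 printed
rows), so computed positive rates differ there by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable
import warnings

import numpy as np
import pandas as pd

from .reference_panels import packaged_path

SITES = ("Collingham", "Driel", "Good Hope", "KwaGandaganda", "Maqonqo",
         "Mgede", "Mhlwazini", "Mzinyashana", "Ndondondwane", "Nkupe", "Wosi")
FARMER_SITES = frozenset({"KwaGandaganda", "Ndondondwane", "Wosi"})
SITE_ALIASES = {"Wozi": "Wosi"}

BOVID_SIZE_CLASSES = ("BOV I", "BOV II", "BOV III", "BOV IV")
_HEAT_RE = re.compile(r"heat|calcin", re.IGNORECASE)


class AssemblageError(ValueError):
    pass


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Half-up rounding (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _read_fixture(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def normalise_site(name: str) -> str:
    name = SITE_ALIASES.get(name, name)
    if name not in SITES:
        raise AssemblageError(f"unknown site {name!r}")
    return name


# --------------------------------------------------------------------------
# Dates and tool records


@dataclass(frozen=True)
class DateSpec:
    """A parsed radiocarbon-style date string (uncalibrated years BP)."""

    relation: str  # at | younger_than | older_than | range | undated
    value_bp: float | None = None
    error_bp: float = 0.0
    value2_bp: float | None = None  # upper bound of a range

    def __post_init__(self) -> None:
        if self.relation == "range" and not (
                self.value_bp is not None and self.value2_bp is not None
                and self.value_bp < self.value2_bp):
            raise AssemblageError("range requires value_bp < value2_bp")
        if self.error_bp < 0:
            raise AssemblageError("error_bp must be >= 0")


_DATE_RE = re.compile(
    r"^(?P<rel>[<>]?)\s*(?P<v>\d+)(?:\s*±\s*(?P<err>\d+))?"
    r"(?:\s*[–\-]\s*(?P<v2>\d+))?\s*BP$")


def parse_date(text: str) -> DateSpec:
    """Parse printed date strings: ``1775±40 BP``, ``<1080±60 BP``,
    ``1770–1880 BP``, ``6300 BP``; anything else is *undated* (with a warning
    for non-empty strings)."""
    text = text.strip()
    if not text or text.lower() == "undated":
        return DateSpec("undated")
    m = _DATE_RE.match(text)
    if m is None:
        warnings.warn(f"unparseable date {text!r}; recorded as undated")
        return DateSpec("undated")
    v = float(m.group("v"))
    err = float(m.group("err") or 0)
    if m.group("v2"):
        return DateSpec("range", v, err, float(m.group("v2")))
    rel = {"<": "younger_than", ">": "older_than", "": "at"}[m.group("rel")]
    return DateSpec(rel, v, err)


@dataclass
class ToolRecord:
    """One sampled bone point from the identification table."""

    site: str
    accession: str
    date_text: str
    date: DateSpec
    period: str  # pre-contact | contact | unknown
    zooms_code: str
    id_taxon: str | None  # clade label as printed, None = no result
    observations: str
    heated: bool
    placeholder: bool = False  # padded record absent from the printed table

    @property
    def identified(self) -> bool:
        return self.id_taxon is not None


def _norm_period(text: str) -> str:
    t = text.strip().lower()
    if t in ("pre-contact", "precontact"):
        return "pre-contact"
    if t == "contact":
        return "contact"
    return "unknown"


def load_tool_table(path: str | Path | None = None,
                    pad_to_sampling: bool = True) -> list[ToolRecord]:
    """Load the per-specimen identification table.

    With ``pad_to_sampling`` (default), per-site record counts are padded up to
    the sampling table with explicit no-result placeholder records, so the
    roster covers every sampled specimen (the printed identification table
    omits one KwaGandaganda specimen).
    """
    df = _read_fixture(Path(path) if path else packaged_path("tool_records.tsv"))
    records: list[ToolRecord] = []
    for _, row in df.iterrows():
        ident = row["id"].strip()
        records.append(ToolRecord(
            site=normalise_site(row["site"]),
            accession=row["accession"],
            date_text=row["date"],
            date=parse_date(row["date"]),
            period=_norm_period(row["period"]),
            zooms_code=row["zooms_code"],
            id_taxon=None if ident in ("", "-") else ident,
            observations=row["observations"],
            heated=bool(_HEAT_RE.search(row["observations"])),
        ))
    if pad_to_sampling:
        sampling = load_sampling_table()
        have = pd.Series([r.site for r in records]).value_counts()
        for _, srow in sampling.iterrows():
            missing = int(srow["n_sampled"]) - int(have.get(srow["site"], 0))
            for k in range(missing):
                records.append(ToolRecord(
                    site=srow["site"], accession="(not listed)", date_text="",
                    date=DateSpec("undated"), period="unknown",
                    zooms_code=f"{srow['site']}-pad{k + 1}", id_taxon=None,
                    observations="sampled specimen absent from the printed "
                                 "identification table", heated=False,
                    placeholder=True))
    return records


def load_faunal_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the faunal MNI table.

    Columns: taxon, common_name, tribe_printed, tribe (normalised), then one
    column per site holding an integer MNI, ``X`` (presence only, from
    NISP-only reports) or empty. Size-class rows (BOV I-IV) are retained but
    never contribute to tribe aggregates.
    """
    df = _read_fixture(Path(path) if path else packaged_path("faunal_mni.tsv"))
    for site in df.columns[4:]:
        normalise_site(site)
    bad = df[df.columns[4:]].apply(
        lambda col: ~col.isin(["", "X"]) & ~col.str.fullmatch(r"\d+"))
    if bad.any().any():
        raise AssemblageError("faunal table cells must be integer, 'X' or empty")
    df["size_class"] = df["taxon"].isin(BOVID_SIZE_CLASSES)
    return df


def load_sampling_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the sampling table: site, shaft_fragments, n_sampled, pct_printed."""
    df = _read_fixture(Path(path) if path else packaged_path("sampling.tsv"))
    df["site"] = df["site"].map(normalise_site)
    df["shaft_fragments"] = df["shaft_fragments"].astype(int)
    df["n_sampled"] = df["n_sampled"].astype(int)
    return df


def load_positive_rate_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the printed per-site positive-rate table (validation reference)."""
    df = _read_fixture(Path(path) if path else packaged_path("positive_rates.tsv"))
    df["site"] = df["site"].map(normalise_site)
    df["n_positive"] = df["n_positive"].astype(int)
    df["pct_printed"] = df["pct_printed"].astype(float)
    return df


def load_site_table(path: str | Path | None = None) -> pd.DataFrame:
    df = _read_fixture(Path(path) if path else packaged_path("sites.tsv"))
    df["worked_bone_n"] = df["worked_bone_n"].astype(int)
    return df


# --------------------------------------------------------------------------
# Clade plumbing

# Tool identifications are either tribe labels or genus/family labels; a
# faunal row belongs to a tool clade when its normalised tribe matches, or its
# taxon name starts with the genus, or equals the family label.
TRIBE_OF_GENUS = {"Syncerus": "Bovini", "Giraffa": None, "Equus": None,
                  "Aonyx": None, "Leporidae": None}


def fauna_members(fauna: pd.DataFrame, clade: str) -> pd.DataFrame:
    """Faunal rows that fall inside a tool-identification clade label."""
    named = fauna[~fauna["size_class"]]
    mask = (named["tribe"] == clade) \
        | (named["taxon"].str.split().str[0] == clade) \
        | (named["taxon"] == clade)
    return named[mask]


def _site_has_clade(fauna: pd.DataFrame, site: str, clade: str) -> bool:
    members = fauna_members(fauna, clade)
    return bool((members[site] != "").any())


# --------------------------------------------------------------------------
# Analytics


def positives_by_site(tools: Iterable[ToolRecord]) -> pd.DataFrame:
    """Per-site sampled/identified counts and positive percentage (half-up)."""
    rows = []
    tools = list(tools)
    for site in SITES:
        mine = [t for t in tools if t.site == site]
        n_id = sum(t.identified for t in mine)
        pct = round_half_up(100 * n_id / len(mine), 1) if mine else float("nan")
        rows.append({"site": site, "n_sampled": len(mine),
                     "n_identified": n_id, "pct": pct})
    df = pd.DataFrame(rows)
    total_n = int(df["n_sampled"].sum())
    total_id = int(df["n_identified"].sum())
    df.loc[len(df)] = {"site": "TOTAL", "n_sampled": total_n,
                       "n_identified": total_id,
                       "pct": round_half_up(100 * total_id / total_n, 1)
                       if total_n else float("nan")}
    return df


def tribe_composition(tools: Iterable[ToolRecord], by: str | None = None,
                      rollup_species: bool = False) -> pd.DataFrame:
    """Counts and integer percentage shares of identified bone points by clade.

    Identifications are grouped at tribe rank where the printed label is a
    tribe; genus/family labels stay separate unless ``rollup_species`` merges
    those with a known tribe (Syncerus -> Bovini). ``by`` optionally splits
    the table per ``"site"`` or ``"period"``.
    """
    if by not in (None, "site", "period"):
        raise ValueError("by must be None, 'site' or 'period'")
    ids = [t for t in tools if t.identified]
    rows = []
    for t in ids:
        clade = t.id_taxon
        if rollup_species and TRIBE_OF_GENUS.get(clade):
            clade = TRIBE_OF_GENUS[clade]
        rows.append({"clade": clade,
                     "group": getattr(t, by) if by else "all"})
    if not rows:
        return pd.DataFrame(columns=["group", "clade", "count", "share_pct"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["group", "clade"]).size().rename("count").reset_index())
    totals = out.groupby("group")["count"].transform("sum")
    out["share_pct"] = [round_half_up(100 * c / n, 0)
                        for c, n in zip(out["count"], totals)]
    out["share_pct"] = out["share_pct"].astype(int)
    keys, asc = ["count", "clade"], [False, True]
    if by is None:
        out = out.drop(columns="group")
    else:
        keys, asc = ["group"] + keys, [True] + asc
    return out.sort_values(keys, ascending=asc, kind="stable").reset_index(drop=True)


def tools_absent_in_fauna(tools: Iterable[ToolRecord],
                          fauna: pd.DataFrame) -> pd.DataFrame:
    """Tool clades at sites where the unmodified fauna shows no member.

    A clade counts as absent at a site when no faunal row belonging to it has
    an MNI count or a presence mark there.
    """
    rows = []
    ids = [t for t in tools if t.identified]
    for (site, clade), group in pd.DataFrame(
            [{"site": t.site, "clade": t.id_taxon} for t in ids]).groupby(
            ["site", "clade"]):
        if not _site_has_clade(fauna, site, clade):
            rows.append({"site": site, "clade": clade, "n_points": len(group)})
    return pd.DataFrame(rows, columns=["site", "clade", "n_points"])


@dataclass
class PeriodBreakdown:
    table: pd.DataFrame
    ratio: float | None  # pre-contact : contact identified, when both nonzero


def period_breakdown(tools: Iterable[ToolRecord],
                     site_filter: Iterable[str] | None = None) -> PeriodBreakdown:
    """Identified records split by printed period, with per-clade counts."""
    tools = list(tools)
    if site_filter is not None:
        allowed = {normalise_site(s) for s in site_filter}
        tools = [t for t in tools if t.site in allowed]
    ids = [t for t in tools if t.identified]
    periods = ("pre-contact", "contact", "unknown")
    clades = sorted({t.id_taxon for t in ids})
    rows = []
    for period in periods:
        mine = [t for t in ids if t.period == period]
        row = {"period": period, "n_identified": len(mine)}
        for clade in clades:
            row[clade] = sum(t.id_taxon == clade for t in mine)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("period")
    pre = int(table.loc["pre-contact", "n_identified"])
    con = int(table.loc["contact", "n_identified"])
    ratio = pre / con if pre and con else None
    return PeriodBreakdown(table, ratio)


def fauna_tribe_shares(fauna: pd.DataFrame, include_presence_as: int = 0,
                       include_caprini: bool = True, include_bovini: bool = True,
                       sites: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-tribe MNI totals and percentage shares of the named bovid fauna.

    Size-class rows never contribute. ``include_presence_as`` counts each
    presence-only 'X' cell as 0 (default) or 1; Caprini (domestic stock) and
    Bovini can be excluded from the denominator — the printed summary
    percentages do not state their convention, so all three choices are
    explicit here.
    """
    if include_presence_as not in (0, 1):
        raise ValueError("include_presence_as must be 0 or 1")
    site_cols = [s for s in SITES if sites is None or s in
                 {normalise_site(x) for x in sites}]
    bovids = fauna[(fauna["tribe"] != "") & ~fauna["size_class"]]
    if not include_caprini:
        bovids = bovids[bovids["tribe"] != "Caprini"]
    if not include_bovini:
        bovids = bovids[bovids["tribe"] != "Bovini"]

    def cell(v: str) -> int:
        if v == "":
            return 0
        if v == "X":
            return include_presence_as
        return int(v)

    totals: dict[str, int] = {}
    for _, row in bovids.iterrows():
        totals[row["tribe"]] = totals.get(row["tribe"], 0) + sum(
            cell(row[s]) for s in site_cols)
    grand = sum(totals.values())
    out = pd.DataFrame(
        [{"tribe": k, "mni_total": v,
          "share_pct": round_half_up(100 * v / grand, 1) if grand else float("nan")}
         for k, v in totals.items()])
    return out.sort_values("mni_total", ascending=False).reset_index(drop=True)


def sampling_fractions(sampling: pd.DataFrame) -> pd.DataFrame:
    """Percent of shaft fragments sampled per site plus an overall row."""
    df = sampling.copy()
    df["pct"] = [round_half_up(100 * s / t, 1) if t else float("nan")
                 for s, t in zip(df["n_sampled"], df["shaft_fragments"])]
    tot_f = int(df["shaft_fragments"].sum())
    tot_s = int(df["n_sampled"].sum())
    df.loc[len(df)] = {"site": "TOTAL", "shaft_fragments": tot_f,
                       "n_sampled": tot_s, "pct_printed": "",
                       "pct": round_half_up(100 * tot_s / tot_f, 1)
                       if tot_f else float("nan")}
    return df[["site", "shaft_fragments", "n_sampled", "pct"]]


def weighted_positive_rate(tools: Iterable[ToolRecord],
                           sampling: pd.DataFrame) -> pd.DataFrame:
    """Per-site positive rates weighted by each site's share of bone points.

    Weights are shaft-fragment counts normalised over all sites (they sum to
    1), so the weighted values are invariant to rescaling every site's total.
    """
    pos = positives_by_site(tools).set_index("site")
    df = sampling.copy()
    total = df["shaft_fragments"].sum()
    df["weight"] = df["shaft_fragments"] / total
    df["positive_pct"] = [
        100 * pos.loc[s, "n_identified"] / pos.loc[s, "n_sampled"]
        if pos.loc[s, "n_sampled"] else float("nan") for s in df["site"]]
    df["weighted_pct"] = df["weight"] * df["positive_pct"]
    return df[["site", "weight", "positive_pct", "weighted_pct"]]


def _total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def preference_permutation_test(tools: Iterable[ToolRecord], fauna: pd.DataFrame,
                                n_perm: int = 1000, seed: int | None = None,
                                include_presence_as: int = 0):
    """Permutation test of tool-taxon selection against the faunal background.

    The observed statistic is the total-variation distance between the tribe
    composition of identified bone points (rolled up to bovid tribes; non-bovid
    identifications dropped) and the faunal MNI tribe shares. The null draws
    the same number of identifications multinomially from the faunal shares
    ``n_perm`` times; the p-value is ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    shares = fauna_tribe_shares(fauna, include_presence_as=include_presence_as)
    if shares.empty:
        raise AssemblageError("empty faunal table")
    fauna_tribes = shares["tribe"].tolist()
    fauna_p = shares["mni_total"].to_numpy(float)
    if fauna_p.sum() == 0:
        raise AssemblageError("faunal table has zero total MNI")
    fauna_p /= fauna_p.sum()

    counts = {tr: 0 for tr in fauna_tribes}
    n_tools = 0
    for t in tools:
        if not t.identified:
            continue
        clade = TRIBE_OF_GENUS.get(t.id_taxon, t.id_taxon)
        if clade in counts:
            counts[clade] += 1
            n_tools += 1
    if n_tools == 0:
        raise AssemblageError("no identified tools fall in the faunal tribes")
    tool_p = np.array([counts[tr] for tr in fauna_tribes], float) / n_tools

    observed = _total_variation(tool_p, fauna_p)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_tools, fauna_p, size=n_perm) / n_tools
    null = 0.5 * np.abs(draws - fauna_p).sum(axis=1)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return observed, p
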