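"""Massively parallel reporter assay (MPRA) quantification.

Enhancer activity is read out as the ratio of normalized RNA to normalized
plasmid-DNA barcode abundance per construct.  The module covers the full
desk-side analysis: barcode-to-construct assignment, counts-per-million
normalization, representation and replicate QC, the per-position mutagenesis
effect map across the element, and Welch-t comparisons of each construct (or
motif) against the wild-type element with Benjamini-Hochberg correction.

The experimental design emulated throughout is a pooled library of one
wild-type element plus constructs carrying either a deletion of a predicted
transcription-factor binding site, a point mutation of its most conserved
residue, or a serial 5'/3' end deletion, each introduced into several
independent plasmid libraries and transfected into several wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, welch_t

__all__ = [
    "ConstructDesign",
    "BarcodeCountMatrix",
    "ActivityTable",
    "assign_barcodes",
    "normalize_counts",
    "activity_ratio",
    "qc_filter",
    "mutagenesis_scan",
    "test_vs_wt",
    "read_design",
    "write_design",
]

CATEGORIES = (
    "wt",
    "tf_deletion",
    "point_mutation",
    "end_deletion_5p",
    "end_deletion_3p",
    "control_minP",
)

#: exclusion reason codes used in ActivityTable.reasons
REASON_LOW_DNA = "low_dna"
REASON_ZERO_DNA = "zero_dna"
REASON_WT_REPLICATE = "wt_replicate_outlier"
REASON_ZERO_TOTAL = "zero_total_replicate"


@dataclass(frozen=True)
class ConstructDesign:
    """One reporter construct in the pooled library.

    ``mutated_interval`` is a 1-based inclusive (start, end) genomic interval
    (hg38 convention) giving the element positions altered by this construct;
    it is ``None`` for the wild-type element and minimal-promoter control.
    """

    construct_id: str
    category: str = "wt"
    mutated_interval: tuple[int, int] | None = None
    motif_label: str = ""
    barcode_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.mutated_interval is not None:
            s, e = self.mutated_interval
            if e < s:
                raise ValueError("mutated_interval end < start")


@dataclass
class BarcodeCountMatrix:
    """Construct x replicate integer counts for one assay (DNA or RNA).

    ``replicates`` carries the library/well layout: index = replicate id,
    columns ``library`` (1..n_libraries) and ``well`` (1..n_wells).
    """

    assay: str
    counts: pd.DataFrame
    replicates: pd.DataFrame
    unmatched: pd.Series | None = None

    def __post_init__(self):
        if self.assay not in ("DNA", "RNA"):
            raise ValueError("assay must be 'DNA' or 'RNA'")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class ActivityTable:
    """Per-construct, per-replicate mRNA/DNA activity with inclusion flags.

    ``ratio`` is only meaningful where ``included`` is True; excluded cells
    carry a reason code in ``reasons`` (empty string = included).
    """

    ratio: pd.DataFrame
    dna_cpm: pd.DataFrame
    rna_cpm: pd.DataFrame
    included: pd.DataFrame
    reasons: pd.DataFrame
    replicates: pd.DataFrame

    def included_values(self, construct_ids: Sequence[str] | None = None) -> np.ndarray:
        """Flat array of included activity values, optionally restricted."""
        r = self.ratio if construct_ids is None else self.ratio.loc[list(construct_ids)]
        m = self.included if construct_ids is None else self.included.loc[list(construct_ids)]
        vals = r.to_numpy()[m.to_numpy()]
        return vals[~np.isnan(vals)]


def _check_disjoint_barcodes(design: Sequence[ConstructDesign]) -> dict[str, str]:
    """Barcode -> construct map; raises on a barcode shared by two constructs."""
    lookup: dict[str, str] = {}
    for c in design:
        for bc in c.barcode_ids:
            if bc in lookup:
                raise ValueError(
                    f"barcode {bc!r} assigned to both {lookup[bc]!r} and {c.construct_id!r}")
            lookup[bc] = c.construct_id
    ids = [c.construct_id for c in design]
    if len(set(ids)) != len(ids):
        raise ValueError("construct_id values must be unique")
    return lookup


def assign_barcodes(
    barcode_reads: Mapping[str, Iterable[tuple[str, int]]] | Iterable[tuple[str, int]],
    design: Sequence[ConstructDesign],
    assay: str,
    replicates: pd.DataFrame | None = None,
) -> BarcodeCountMatrix:
    """Collapse barcode-level read counts to construct-level counts.

    ``barcode_reads`` is either a single stream of ``(barcode, count)`` pairs
    (one replicate, id ``"rep1"``) or a mapping replicate id -> stream.
    Barcodes not present in the design are tallied per replicate in
    ``unmatched`` and reported, never silently dropped.
    """
    lookup = _check_disjoint_barcodes(design)
    if not isinstance(barcode_reads, Mapping):
        barcode_reads = {"rep1": barcode_reads}
    construct_ids = [c.construct_id for c in design]
    counts = pd.DataFrame(0, index=construct_ids, columns=list(barcode_reads),
                          dtype=np.int64)
    unmatched = pd.Series(0, index=list(barcode_reads), dtype=np.int64)
    for rep, stream in barcode_reads.items():
        for bc, n in stream:
            if n < 0:
                raise ValueError("negative read count")
            cid = lookup.get(bc)
            if cid is None:
                unmatched[rep] += n
            else:
                counts.loc[cid, rep] += n
    if replicates is None:
        replicates = pd.DataFrame(
            {"library": 1, "well": np.arange(1, counts.shape[1] + 1)},
            index=counts.columns)
    return BarcodeCountMatrix(assay=assay, counts=counts,
                              replicates=replicates, unmatched=unmatched)


def normalize_counts(m: BarcodeCountMatrix) -> pd.DataFrame:
    """Counts per million within each replicate.

    Each replicate column is divided by its total barcode-read count and
    scaled to 1e6, so column sums are exactly 1e6.  A zero-total replicate
    cannot be normalized: its column is NaN and a warning is raised so the
    QC step can exclude it.
    """
    totals = m.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"replicates with zero total counts: {list(totals.index[zero])}",
            stacklevel=2)
    totals[zero] = np.nan
    return m.counts.div(totals, axis=1) * 1e6


def activity_ratio(
    rna_norm: pd.DataFrame,
    dna_norm: pd.DataFrame,
    replicates: pd.DataFrame | None = None,
) -> ActivityTable:
    """mRNA/DNA activity per construct and replicate.

    Cells with zero (or unnormalizable) DNA are marked undefined and
    excluded with a reason code; no pseudocount is applied.
    """
    if not rna_norm.index.equals(dna_norm.index) or not rna_norm.columns.equals(dna_norm.columns):
        raise ValueError("RNA and DNA matrices must share constructs and replicates")
    if replicates is None:
        replicates = pd.DataFrame(
            {"library": 1, "well": np.arange(1, rna_norm.shape[1] + 1)},
            index=rna_norm.columns)
    dna = dna_norm.to_numpy(dtype=float)
    rna = rna_norm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dna > 0, rna / dna, np.nan)
    included = pd.DataFrame(dna > 0, index=rna_norm.index, columns=rna_norm.columns)
    reasons = pd.DataFrame("", index=rna_norm.index, columns=rna_norm.columns)
    reasons = reasons.mask(dna == 0, REASON_ZERO_DNA)
    reasons = reasons.mask(np.isnan(dna), REASON_ZERO_TOTAL)
    return ActivityTable(
        ratio=pd.DataFrame(ratio, index=rna_norm.index, columns=rna_norm.columns),
        dna_cpm=dna_norm.copy(), rna_cpm=rna_norm.copy(),
        included=included, reasons=reasons, replicates=replicates)


def qc_filter(
    act: ActivityTable,
    wt_construct: str = "WT",
    min_norm_count: float = 100.0,
    wt_sd_k: float = 1.0,
    filter_rna: bool = False,
) -> tuple[ActivityTable, dict]:
    """Apply the representation and replicate-consistency exclusions.

    Rule (a): a cell is excluded when its normalized DNA count is below
    ``min_norm_count`` CPM (optionally also on the RNA assay via
    ``filter_rna``) — constructs with low barcode representation carry no
    reliable activity estimate.

    Rule (b): an entire technical replicate is excluded when the wild-type
    element's activity in that replicate deviates from the mean wild-type
    activity across its library's replicates by at least ``wt_sd_k`` sample
    standard deviations (computed within the library).  When the within-
    library SD is zero no replicate is excluded.

    Returns the filtered table plus a QC report with per-rule counts.
    """
    if wt_construct not in act.ratio.index:
        raise ValueError(f"WT construct {wt_construct!r} not present")
    included = act.included.copy()
    reasons = act.reasons.copy()

    low_dna = (act.dna_cpm < min_norm_count) & included
    included &= ~low_dna
    reasons = reasons.mask(low_dna, REASON_LOW_DNA)
    n_low_rna = 0
    if filter_rna:
        low_rna = (act.rna_cpm < min_norm_count) & included
        included &= ~low_rna
        reasons = reasons.mask(low_rna, REASON_LOW_DNA)
        n_low_rna = int(low_rna.to_numpy().sum())

    wt_ok = included.loc[wt_construct]
    if not wt_ok.any():
        raise ValueError("no WT replicates survive the representation filter")

    # Rule (b): within each library, flag replicates whose WT activity is an
    # outlier relative to that library's replicate mean.
    dropped_reps: list[str] = []
    wt_act = act.ratio.loc[wt_construct]
    for lib, reps in act.replicates.groupby("library").groups.items():
        reps = [r for r in reps if wt_ok.get(r, False)]
        if len(reps) < 2:
            continue
        vals = wt_act[reps].astype(float)
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        dev = (vals - vals.mean()).abs()
        dropped_reps.extend(vals.index[dev >= wt_sd_k * sd])
    for rep in dropped_reps:
        newly = included[rep].copy()
        included[rep] = False
        reasons.loc[newly, rep] = REASON_WT_REPLICATE

    report = {
        "n_low_dna": int(low_dna.to_numpy().sum()),
        "n_low_rna": n_low_rna,
        "n_wt_replicate_excluded": len(dropped_reps),
        "excluded_replicates": sorted(dropped_reps),
        "min_norm_count": float(min_norm_count),
        "wt_sd_k": float(wt_sd_k),
    }
    out = replace(act, included=included, reasons=reasons)
    return out, report


def mutagenesis_scan(
    act: ActivityTable,
    design: Sequence[ConstructDesign],
    element_interval: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-position effect map across the element.

    Each position's value on a track is the mean over all included
    (construct, replicate) activities of constructs whose mutated interval
    covers that position.  Deletion-style categories and point mutations are
    reported as separate tracks, mirroring the two marker series of a
    mutagenesis scan figure.  Positions covered by no construct are absent
    (gaps), never zero.

    Returns a tidy frame: position, track, mean_activity, sd, n_constructs,
    n_values.
    """
    track_of = {
        "tf_deletion": "deletion", "end_deletion_5p": "deletion",
        "end_deletion_3p": "deletion", "point_mutation": "point_mutation",
    }
    by_cat = {}
    for c in design:
        if c.category in ("wt", "control_minP"):
            continue
        if c.mutated_interval is None:
            raise ValueError(f"construct {c.construct_id} has no mutated_interval")
        if c.construct_id not in act.ratio.index:
            continue
        if element_interval is not None:
            s, e = c.mutated_interval
            if s < element_interval[0] or e > element_interval[1]:
                raise ValueError(
                    f"construct {c.construct_id} interval outside element")
        by_cat.setdefault(track_of[c.category], []).append(c)

    rows = []
    for track, constructs in by_cat.items():
        cover: dict[int, list[str]] = {}
        for c in constructs:
            s, e = c.mutated_interval
            for pos in range(s, e + 1):
                cover.setdefault(pos, []).append(c.construct_id)
        for pos in sorted(cover):
            vals = np.concatenate([
                act.included_values([cid]) for cid in cover[pos]]) \
                if cover[pos] else np.array([])
            if vals.size == 0:
                continue
            rows.append({
                "position": pos, "track": track,
                "mean_activity": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_constructs": len(cover[pos]), "n_values": int(vals.size),
            })
    return pd.DataFrame(rows, columns=["position", "track", "mean_activity",
                                       "sd", "n_constructs", "n_values"])


def test_vs_wt(
    act: ActivityTable,
    design: Sequence[ConstructDesign],
    wt_construct: str = "WT",
    grouping: str = "construct",
) -> pd.DataFrame:
    """Welch t test of each group's activities against the wild-type element.

    ``grouping`` is ``"construct"`` (one test per non-WT construct) or
    ``"motif_label"`` (constructs pooled by motif).  BH adjustment is applied
    across all groups tested in this call.  Groups with fewer than two
    included values are skipped with a warning.
    """
    if grouping not in ("construct", "motif_label"):
        raise ValueError("grouping must be 'construct' or 'motif_label'")
    wt_vals = act.included_values([wt_construct])
    if wt_vals.size < 2:
        raise ValueError("need >= 2 included WT activities")
    groups: dict[str, list[str]] = {}
    for c in design:
        if c.construct_id == wt_construct or c.construct_id not in act.ratio.index:
            continue
        key = c.construct_id if grouping == "construct" else (c.motif_label or c.construct_id)
        groups.setdefault(key, []).append(c.construct_id)

    rows = []
    for name, cids in groups.items():
        vals = act.included_values(cids)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has < 2 included values; skipped",
                          stacklevel=2)
            continue
        res = welch_t(vals, wt_vals)
        rows.append({"group": name, "n": int(vals.size),
                     "mean_activity": float(vals.mean()),
                     "wt_mean_activity": float(wt_vals.mean()),
                     "t": res.statistic, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows, columns=["group", "n", "mean_activity",
                                      "wt_mean_activity", "t", "df", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = []
    return out


# ---------------------------------------------------------------------------
# design-table I/O (TSV: construct_id, category, start, end, motif_label,
# barcodes comma-joined)

def write_design(design: Sequence[ConstructDesign], path) -> None:
    rows = []
    for c in design:
        s, e = c.mutated_interval if c.mutated_interval else ("", "")
        rows.append({"construct_id": c.construct_id, "category": c.category,
                     "start": s, "end": e, "motif_label": c.motif_label,
                     "barcodes": ",".join(sorted(c.barcode_ids))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path) -> list[ConstructDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"motif_label": str, "barcodes": str},
                     keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        interval = None
        if str(r.get("start", "")) not in ("", "nan"):
            interval = (int(r["start"]), int(r["end"]))
        barcodes = frozenset(b for b in str(r.get("barcodes", "")).split(",") if b)
        out.append(ConstructDesign(r["construct_id"], r["category"], interval,
                                   str(r.get("motif_label", "")), barcodes))
    return out
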