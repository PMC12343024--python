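"""Gene-set partitioning and ω-distribution comparison between lineages.

Genes are partitioned into pigmentation-specific / pigmentation-related
/ background sets; per-branch ω distributions are summarized (mean and
median ω, median Ka and Ks) and contrasted between lineages with the
two-sided Wilcoxon rank-sum test, mirroring the violin-plot comparison
of cave vs surface selective pressure.  Genes with undefined ω (Ks = 0
or unconverged fits) are excluded from the statistics and counted
separately — coercing them to 0 or to an arbitrary ceiling would bias
the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_evolution import CodonAlignment, OmegaEstimate
from .synthetic_data import GeneRecord, LABELS

__all__ = [
    "ComparisonResult",
    "OmegaSummary",
    "partition_genes",
    "summarize_omega",
    "wilcoxon_rank_sum",
    "compare_groups",
    "concatenate_alignments",
    "omega_long_table",
]


@dataclass(frozen=True)
class OmegaSummary:
    """Distribution summary of ω (and Ka/Ks medians) for one gene set x branch."""

    mean_omega: float | None
    median_omega: float | None
    median_ka: float | None
    median_ks: float | None
    n_defined: int
    n_undefined: int

    @property
    def empty(self) -> bool:
        return self.n_defined == 0


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided rank-sum comparison of two ω samples.

    Group descriptors are (label, branch) pairs; undefined-ω genes are
    excluded from the test and reported via the n_undefined counts.
    """

    group_a: tuple[str, str]
    group_b: tuple[str, str]
    mean_a: float | None
    mean_b: float | None
    median_a: float | None
    median_b: float | None
    U: float
    p_value: float
    n_a: int
    n_b: int
    n_undefined_a: int = 0
    n_undefined_b: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def partition_genes(
    records, label_table=None
) -> dict[str, list[GeneRecord]]:
    """Partition gene records by set label.

    ``label_table`` optionally overrides record labels: a mapping
    gene_id → label, or a DataFrame with columns gene_id/label.
    Unknown gene_ids in the table are reported (returned partition has
    an ``"_unknown_in_table"`` attribute-free convention: they raise no
    error but are listed in the function's second-class output — see
    ``partition_report``).  Duplicate gene_ids with conflicting labels
    raise ``ValueError``.
    """
    part, _ = partition_report(records, label_table)
    return part


def partition_report(
    records, label_table=None
) -> tuple[dict[str, list[GeneRecord]], list[str]]:
    """Like :func:`partition_genes` but also return unknown table ids."""
    overrides: dict[str, str] = {}
    if label_table is not None:
        if isinstance(label_table, pd.DataFrame):
            items = list(zip(label_table["gene_id"], label_table["label"]))
        elif hasattr(label_table, "items"):
            items = list(label_table.items())
        else:
            items = list(label_table)
        for gid, lab in items:
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r} for gene {gid!r}")
            if gid in overrides and overrides[gid] != lab:
                raise ValueError(
                    f"gene {gid!r} assigned conflicting labels "
                    f"{overrides[gid]!r} and {lab!r}"
                )
            overrides[gid] = lab
    records = list(records)
    known_ids = {r.gene_id for r in records}
    unknown = sorted(set(overrides) - known_ids)
    partition: dict[str, list[GeneRecord]] = {lab: [] for lab in LABELS}
    for r in records:
        lab = overrides.get(r.gene_id, r.label)
        if lab not in LABELS:
            raise ValueError(f"record {r.gene_id!r} has unknown label {lab!r}")
        partition[lab].append(r)
    return partition, unknown


def _defined_estimates(records, branch: str):
    defined: list[OmegaEstimate] = []
    undefined = 0
    for r in records:
        est = r.estimates.get(branch)
        if est is None:
            raise ValueError(
                f"gene {r.gene_id!r} has no estimate for branch {branch!r}"
            )
        if est.omega is None or not np.isfinite(est.omega):
            undefined += 1
        else:
            defined.append(est)
    return defined, undefined


def summarize_omega(records, branch: str) -> OmegaSummary:
    """Mean/median ω and median Ka, Ks over genes with defined values.

    An all-undefined input yields a flagged-empty summary rather than an
    exception.
    """
    defined, undefined = _defined_estimates(records, branch)
    if not defined:
        return OmegaSummary(None, None, None, None, 0, undefined)
    omegas = np.array([e.omega for e in defined])
    kas = np.array([e.ka for e in defined if np.isfinite(e.ka)])
    kss = np.array([e.ks for e in defined if np.isfinite(e.ks)])
    return OmegaSummary(
        mean_omega=float(omegas.mean()),
        median_omega=float(np.median(omegas)),
        median_ka=float(np.median(kas)) if kas.size else None,
        median_ks=float(np.median(kss)) if kss.size else None,
        n_defined=len(defined),
        n_undefined=undefined,
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact U distribution when min(n_x, n_y) ≤ 10 and the data
    are tie-free, otherwise the normal approximation with tie and
    continuity corrections.  Two identical constant samples give p = 1
    by convention.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    records_a, branch_a: str, records_b, branch_b: str,
    label_a: str = "a", label_b: str = "b",
) -> ComparisonResult:
    """Rank-sum comparison of per-gene ω between two (set, branch) groups."""
    defined_a, undef_a = _defined_estimates(records_a, branch_a)
    defined_b, undef_b = _defined_estimates(records_b, branch_b)
    xs = [e.omega for e in defined_a]
    ys = [e.omega for e in defined_b]
    U, p = wilcoxon_rank_sum(xs, ys)
    return ComparisonResult(
        group_a=(label_a, branch_a),
        group_b=(label_b, branch_b),
        mean_a=float(np.mean(xs)) if xs else None,
        mean_b=float(np.mean(ys)) if ys else None,
        median_a=float(np.median(xs)) if xs else None,
        median_b=float(np.median(ys)) if ys else None,
        U=U,
        p_value=p,
        n_a=len(xs),
        n_b=len(ys),
        n_undefined_a=undef_a,
        n_undefined_b=undef_b,
    )


def concatenate_alignments(records) -> CodonAlignment:
    """Site-wise concatenation of gene alignments in input order.

    All alignments must share the same taxon set; taxa are reordered to
    the first record's order.  Per-gene codon boundaries are recorded in
    the returned alignment's ``source_id`` as ``gene:start-end`` spans
    (codon coordinates, 0-based half-open).
    """
    items = list(records)
    if not items:
        raise ValueError("nothing to concatenate")
    alns = [r.alignment if isinstance(r, GeneRecord) else r for r in items]
    taxa = alns[0].taxa
    taxa_set = set(taxa)
    sites: list[tuple[str, ...]] = []
    bounds = []
    pos = 0
    for aln in alns:
        if set(aln.taxa) != taxa_set:
            raise ValueError(
                f"taxon mismatch: {aln.taxa} vs {taxa} in {aln.source_id!r}"
            )
        order = [aln.taxa.index(t) for t in taxa]
        for col in aln.sites:
            sites.append(tuple(col[i] for i in order))
        bounds.append(f"{aln.source_id or 'gene'}:{pos}-{pos + aln.n_codons}")
        pos += aln.n_codons
    return CodonAlignment(
        taxa=taxa, sites=tuple(sites), source_id=";".join(bounds)
    )


def omega_long_table(records, branches=("cave", "surface")) -> pd.DataFrame:
    """Long-format per-gene ω table (violin-plot-ready).

    Columns: gene_id, label, branch, omega, ka, ks, method; undefined ω
    appear as NaN so plotting layers can drop them explicitly.
    """
    rows = []
    for r in records:
        for b in branches:
            est = r.estimates.get(b)
            if est is None:
                continue
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "label": r.label,
                    "branch": b,
                    "omega": np.nan if est.omega is None else est.omega,
                    "ka": est.ka,
                    "ks": est.ks,
                    "method": est.method,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "label", "branch", "omega", "ka", "ks", "method"]
    )
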