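"""Mixed-branch dating of the onset of relaxed selection.

A lineage that spent part of its history under purifying selection
(ω = ω_f) and the remainder evolving neutrally (ω = ω_n, typically 1)
shows a single fitted ω that is the time-weighted average of the two
phases:

    ω_m = ((T − t)·ω_f + t·ω_n) / T

Inverting gives the time since relaxation began:

    t = T · (ω_m − ω_f) / (ω_n − ω_f)

With the surface lineage providing ω_f (its genes never relaxed), the
cave lineage's ω_m, ω_n = 1 and the lineage age T, this dates the cave
colonization — as an upper bound, since complete neutrality is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon_evolution import TreeSpec, fit_branch_model

__all__ = [
    "MixedBranchInputs",
    "DatingResult",
    "omega_mixed_expected",
    "estimate_relaxation_time",
    "date_from_alignments",
]


@dataclass(frozen=True)
class MixedBranchInputs:
    """Inputs of the mixed-branch dating equation.

    ω_f: constrained-phase ω (from the surface lineage); ω_m: fitted ω
    of the mixed (cave) branch; ω_n: neutral-phase ω (1.0 = complete
    neutrality); T: total duration of the mixed branch in My.
    """

    omega_m: float
    omega_f: float
    T: float
    omega_n: float = 1.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.omega_f < 0:
            raise ValueError("omega_f must be >= 0")
        if self.omega_n <= self.omega_f:
            raise ValueError(
                "degenerate mixture: omega_n must exceed omega_f"
            )

    def validate_ordering(self) -> None:
        if self.omega_m < self.omega_f:
            raise ValueError(
                "mixed branch more constrained than functional branch "
                f"(omega_m={self.omega_m} < omega_f={self.omega_f})"
            )
        if self.omega_m > self.omega_n:
            raise ValueError(
                "mixed branch exceeds neutral ceiling "
                f"(omega_m={self.omega_m} > omega_n={self.omega_n})"
            )


@dataclass(frozen=True)
class DatingResult:
    """Estimated time since relaxation, with provenance.

    ``fraction`` is t/T; ``upper_bound_flag`` marks results computed
    under the complete-neutrality assumption (ω_n = 1), which can only
    overestimate t.  ``clamped`` is set when a noisy, out-of-order ω
    pair was clamped to the [0, T] boundary instead of failing.
    """

    t: float
    fraction: float
    upper_bound_flag: bool
    clamped: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


def omega_mixed_expected(
    omega_f: float, omega_n: float, t: float, T: float
) -> float:
    """Expected single-ω of a branch mixing two selective phases.

    Returns ((T − t)·ω_f + t·ω_n) / T — the forward model inverted by
    :func:`estimate_relaxation_time`.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if not (0.0 <= t <= T):
        raise ValueError("require 0 <= t <= T")
    return ((T - t) * omega_f + t * omega_n) / T


def estimate_relaxation_time(
    inputs: MixedBranchInputs, clamp: bool = False
) -> DatingResult:
    """Invert the mixed-branch equation for the relaxation time t.

    Raises on out-of-order ω (ω_m < ω_f, or ω_m > ω_n) unless
    ``clamp=True``, in which case t is clamped to the nearest boundary
    and flagged — the tolerant mode used by the data-driven path where
    sampling noise can violate the ordering.
    """
    clamped = False
    omega_m = inputs.omega_m
    if clamp:
        lo, hi = inputs.omega_f, inputs.omega_n
        if omega_m < lo:
            omega_m, clamped = lo, True
        elif omega_m > hi:
            omega_m, clamped = hi, True
    else:
        inputs.validate_ordering()
    t = inputs.T * (omega_m - inputs.omega_f) / (inputs.omega_n - inputs.omega_f)
    return DatingResult(
        t=t,
        fraction=t / inputs.T,
        upper_bound_flag=inputs.omega_n == 1.0,
        clamped=clamped,
        metadata={
            "omega_m": inputs.omega_m,
            "omega_f": inputs.omega_f,
            "omega_n": inputs.omega_n,
            "T": inputs.T,
        },
    )


def date_from_alignments(
    specific_records,
    tree: TreeSpec,
    T: float,
    omega_n: float = 1.0,
    freq_model: str = "F3x4",
    n_starts: int = 3,
) -> DatingResult:
    """Date relaxation directly from gene alignments.

    Concatenates the pigmentation-specific gene alignments (a single
    long alignment yields a steadier ω than per-gene fits), fits the
    branch model with one free ω per branch, reads ω_f off the surface
    branch and ω_m off the cave branch, and inverts the mixture.
    Out-of-order estimates are clamped and flagged rather than raised:
    a pipeline run must not crash on sampling noise.
    """
    from .selection_comparison import concatenate_alignments  # local: avoid cycle

    concat = concatenate_alignments(specific_records)
    fit = fit_branch_model(concat, tree, n_starts=n_starts, freq_model=freq_model)
    omega_m = fit.estimates["cave"].omega
    omega_f = fit.estimates["surface"].omega
    if omega_m is None or omega_f is None:
        raise ValueError("branch-model fit produced undefined omega")
    inputs = MixedBranchInputs(omega_m=omega_m, omega_f=omega_f, T=T, omega_n=omega_n)
    result = estimate_relaxation_time(inputs, clamp=True)
    result.metadata.update(
        {
            "lnl": fit.lnl,
            "converged": fit.converged,
            "n_codons": concat.n_codons,
            "n_genes": len(list(specific_records)),
            "omega_outgroup": fit.estimates["outgroup"].omega,
        }
    )
    return result
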