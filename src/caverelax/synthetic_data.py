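"""Synthetic inputs for every pipeline stage.

Nothing downstream requires real data: this module simulates

* codon alignments on the cave/surface/outgroup star tree under
  branch-specific ω (GY94 continuous-time Markov chain, exact
  matrix-exponential transition probabilities);
* a "mixed" cave branch that evolves under purifying selection for part
  of its duration and neutrally for the rest — the scenario behind the
  relaxation-dating analysis;
* labelled gene sets (pigmentation-specific / pigmentation-related /
  background) with distinct ω regimes, mirroring the observed contrast
  between gene classes;
* toy gene models carrying the two mutation archetypes seen in the
  cavefish: a 5′ splice-donor replacement with a single alternative
  in-exon GT donor (mitfa-like) and a single-nucleotide T→A change
  creating a premature stop codon (tyrp1a-like).

All randomness flows through explicitly seeded ``numpy`` generators; a
given (config, seed) pair reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codon_evolution import (
    BRANCH_NAMES,
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    GY94Params,
    TreeSpec,
    branch_length_from_time,
    gy94_rate_matrix,
    transition_matrix,
)
from .variant_consequences import GeneModel, Variant

__all__ = [
    "SimulationConfig",
    "MixedBranchScenario",
    "FixtureSpec",
    "GeneRecord",
    "simulate_codon_alignment",
    "simulate_mixed_branch_alignment",
    "generate_gene_sets",
    "default_regimes",
    "default_tree",
    "make_splice_fixture",
    "make_ptc_fixture",
    "mitfa_like_fixture",
    "tyrp1a_like_fixture",
    "DEFAULT_CLOCK_RATE",
]

#: Synonymous substitutions per codon per My.  Chosen so that the surface
#: branch accumulates Ks ≈ 0.1 over the 21.3-My divergence of the cave
#: lineage (≈0.7 synonymous sites per codon under uniform frequencies).
DEFAULT_CLOCK_RATE = 0.0033


def _uniform_freqs() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one codon-alignment simulation.

    ``branch_lengths`` are expected substitutions per codon;
    ``branch_omegas`` maps each of cave/surface/outgroup to its dN/dS.
    """

    n_codons: int
    branch_omegas: dict[str, float]
    branch_lengths: dict[str, float]
    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=_uniform_freqs)
    seed: int = 0

    def __post_init__(self):
        freqs = np.asarray(self.codon_freqs, dtype=float)
        object.__setattr__(self, "codon_freqs", freqs)
        if self.n_codons < 0:
            raise ValueError("n_codons must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if freqs.shape == (64,):
            stop_mass = sum(
                freqs[i]
                for i, c in enumerate(sorted(GENETIC_CODE))
                if c in STOP_CODONS
            )
            if stop_mass > 0:
                raise ValueError("codon_freqs assigns mass to stop codons")
        if freqs.shape != (N_SENSE,):
            raise ValueError(f"codon_freqs must cover the {N_SENSE} sense codons")
        if abs(float(freqs.sum()) - 1.0) > 1e-12:
            raise ValueError("codon_freqs must sum to 1 (within 1e-12)")
        for b in self.branch_omegas:
            if b not in self.branch_lengths:
                raise ValueError(f"branch {b!r} has an omega but no length")
        unknown = set(self.branch_omegas) - set(BRANCH_NAMES)
        if unknown:
            raise ValueError(f"unknown branch name(s): {sorted(unknown)}")
        if any(w < 0 for w in self.branch_omegas.values()):
            raise ValueError("omega must be >= 0")
        if any(l < 0 for l in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")

    def params(self) -> GY94Params:
        return GY94Params(
            kappa=self.kappa,
            omegas=dict(self.branch_omegas),
            codon_freqs=self.codon_freqs,
        )

    def tree(self) -> TreeSpec:
        return TreeSpec(
            branch_lengths={b: self.branch_lengths[b] for b in BRANCH_NAMES},
            branch_labels={b: b for b in BRANCH_NAMES},
        )


@dataclass(frozen=True)
class MixedBranchScenario:
    """Piecewise selective history of the cave branch.

    The branch lasts ``T`` My: the first ``T − t`` My under the
    constrained ω ``omega_f`` and the final ``t`` My under the relaxed
    ω ``omega_n`` (1.0 = complete neutrality).  ``clock_rate`` converts
    My to substitution branch lengths (synonymous subs/codon/My).
    """

    T: float
    t: float
    omega_f: float
    omega_n: float = 1.0
    clock_rate: float = DEFAULT_CLOCK_RATE

    def __post_init__(self):
        if not (0.0 <= self.t <= self.T):
            raise ValueError("require 0 <= t <= T")
        if self.omega_f < 0:
            raise ValueError("omega_f must be >= 0")
        if self.omega_n < self.omega_f:
            raise ValueError("omega_n must be >= omega_f")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be > 0")


def default_tree(
    cave: float = 0.09, surface: float = 0.09, outgroup: float = 0.7
) -> TreeSpec:
    """Star tree with desk-scale branch lengths (substitutions/codon).

    The outgroup branch is long because the zebrafish lineage diverged
    far earlier (~97 Ma) than the two loaches split (~21 Ma).
    """
    return TreeSpec(
        branch_lengths={"cave": cave, "surface": surface, "outgroup": outgroup}
    )


def _sample_tips(
    transition_mats: dict[str, np.ndarray],
    pi: np.ndarray,
    n_codons: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw root states from π, then each tip given the root.

    Sampling is grouped by parent codon so the per-branch draw is a
    single categorical draw per site; branch order is fixed (cave,
    surface, outgroup) so seeds reproduce exactly.
    """
    root = rng.choice(N_SENSE, size=n_codons, p=pi)
    tips: dict[str, np.ndarray] = {}
    for branch in BRANCH_NAMES:
        P = transition_mats[branch]
        # normalize rows defensively (clamped round-off)
        P = P / P.sum(axis=1, keepdims=True)
        child = np.empty(n_codons, dtype=np.int64)
        u = rng.random(n_codons)
        cdf = np.cumsum(P, axis=1)
        for state in np.unique(root):
            mask = root == state
            child[mask] = np.searchsorted(cdf[state], u[mask], side="right")
        np.clip(child, 0, N_SENSE - 1, out=child)
        tips[branch] = child
    return tips


def _alignment_from_indices(
    tips: dict[str, np.ndarray], source_id: str
) -> CodonAlignment:
    n = len(next(iter(tips.values()))) if tips else 0
    sites = tuple(
        tuple(SENSE_CODONS[tips[b][k]] for b in BRANCH_NAMES) for k in range(n)
    )
    return CodonAlignment(taxa=BRANCH_NAMES, sites=sites, source_id=source_id)


def simulate_codon_alignment(
    config: SimulationConfig, tree: TreeSpec | None = None, source_id: str = "sim"
) -> CodonAlignment:
    """Simulate a 3-taxon codon alignment under branch-specific ω.

    Evolution follows the GY94 continuous-time Markov chain: the
    (unobserved) central node is drawn from the equilibrium codon
    distribution and each tip is sampled from the exact transition
    matrix exp(Q_b · t_b) of its branch.  Output contains no gaps and no
    stop codons; identical (config, seed) give identical alignments.
    """
    tree = tree if tree is not None else config.tree()
    missing = set(BRANCH_NAMES) - set(config.branch_omegas)
    if missing:
        raise ValueError(f"branch_omegas missing {sorted(missing)}")
    params = config.params()
    pi = params.codon_freqs
    mats = {
        b: transition_matrix(
            gy94_rate_matrix(params, b), tree.branch_lengths[b], pi
        )
        for b in BRANCH_NAMES
    }
    rng = np.random.default_rng(config.seed)
    if config.n_codons == 0:
        return CodonAlignment(taxa=BRANCH_NAMES, sites=(), source_id=source_id)
    tips = _sample_tips(mats, pi, config.n_codons, rng)
    return _alignment_from_indices(tips, source_id)


def simulate_mixed_branch_alignment(
    scenario: MixedBranchScenario,
    config: SimulationConfig,
    tree: TreeSpec | None = None,
    source_id: str = "sim-mixed",
) -> CodonAlignment:
    """Simulate with a piecewise (purifying → neutral) cave branch.

    The cave branch evolves for ``T − t`` My at ``omega_f`` followed by
    ``t`` My at ``omega_n`` (root-to-tip order: the constrained phase is
    ancestral).  Durations convert to substitution lengths via the
    synonymous clock.  Surface and outgroup branches use ``config`` /
    ``tree`` values unchanged.
    """
    tree = tree if tree is not None else config.tree()
    params = config.params()
    pi = params.codon_freqs
    kappa = config.kappa

    def phase_matrix(omega: float, duration: float) -> np.ndarray:
        length = branch_length_from_time(
            duration, omega, scenario.clock_rate, kappa, pi
        )
        Q = gy94_rate_matrix(
            GY94Params(kappa=kappa, omegas={"x": omega}, codon_freqs=pi), "x"
        )
        return transition_matrix(Q, length, pi)

    P_cave = phase_matrix(scenario.omega_f, scenario.T - scenario.t) @ phase_matrix(
        scenario.omega_n, scenario.t
    )
    mats = {"cave": P_cave}
    for b in ("surface", "outgroup"):
        mats[b] = transition_matrix(
            gy94_rate_matrix(params, b), tree.branch_lengths[b], pi
        )
    rng = np.random.default_rng(config.seed)
    if config.n_codons == 0:
        return CodonAlignment(taxa=BRANCH_NAMES, sites=(), source_id=source_id)
    tips = _sample_tips(mats, pi, config.n_codons, rng)
    return _alignment_from_indices(tips, source_id)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One gene: identifier, set label, alignment, per-branch estimates."""

    gene_id: str
    label: str
    alignment: CodonAlignment
    estimates: dict = field(default_factory=dict)


LABELS = ("specific", "related", "background")


def default_regimes(
    n_codons: int = 500,
    tree: TreeSpec | None = None,
) -> dict[str, SimulationConfig]:
    """ω regimes echoing the observed gene-class contrast.

    Pigmentation-specific genes are relaxed on the cave branch (ω 0.55
    vs 0.25 on the surface branch); pigmentation-related genes stay
    constrained in both lineages; the background sits in between.
    """
    tree = tree if tree is not None else default_tree()
    lengths = dict(tree.branch_lengths)
    omegas = {
        "specific": {"cave": 0.55, "surface": 0.25, "outgroup": 0.25},
        "related": {"cave": 0.25, "surface": 0.19, "outgroup": 0.20},
        "background": {"cave": 0.29, "surface": 0.26, "outgroup": 0.26},
    }
    return {
        label: SimulationConfig(
            n_codons=n_codons,
            branch_omegas=omegas[label],
            branch_lengths=lengths,
        )
        for label in LABELS
    }


def generate_gene_sets(
    n_specific: int,
    n_related: int,
    n_background: int,
    regimes: dict[str, SimulationConfig] | None = None,
    seed: int = 0,
) -> list[GeneRecord]:
    """Simulate a labelled gene set, one alignment per gene.

    Per-gene seeds are spawned from ``seed`` through a single
    ``SeedSequence`` so the whole set is reproducible and genes are
    independent.  Exactly the three labels specific/related/background
    must be present in ``regimes``.
    """
    regimes = regimes if regimes is not None else default_regimes()
    missing = set(LABELS) - set(regimes)
    if missing:
        raise ValueError(f"missing regime(s): {sorted(missing)}")
    counts = {"specific": n_specific, "related": n_related, "background": n_background}
    if any(c < 0 for c in counts.values()):
        raise ValueError("gene counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(counts.values()))
    records: list[GeneRecord] = []
    k = 0
    for label in LABELS:
        for i in range(counts[label]):
            child_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
            k += 1
            cfg = replace(regimes[label], seed=child_seed)
            gene_id = f"{label}_{i:04d}"
            aln = simulate_codon_alignment(cfg, source_id=gene_id)
            records.append(GeneRecord(gene_id=gene_id, label=label, alignment=aln))
    return records


# ---------------------------------------------------------------------------
# Gene-model fixtures (mitfa-like splice event, tyrp1a-like PTC)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a toy gene model carrying one mutation archetype.

    ``alt_donor_offset`` is the distance (nt) from the 3′ end of the
    affected exon to the alternative in-exon GT donor; a multiple of 3
    gives the in-frame mitfa archetype.  ``donor_replacement`` is the
    (reference, replacement) pair placed across the 5′ splice site of
    ``splice_intron_index``.  For the PTC archetype, ``ptc_exon_index``
    and ``ptc_codon_change`` locate a codon rewritten to one mutable to
    a stop by a single T→A change.
    """

    exon_lengths: tuple[int, ...] = (120, 135, 90, 210, 150)
    intron_lengths: tuple[int, ...] = (78, 84, 90, 96)
    splice_intron_index: int = 3  # 0-based: the 4th intron
    alt_donor_offset: int = 63
    donor_replacement: tuple[str, str] = ("CGG", "TATATA")
    ptc_exon_index: int = 5
    ptc_codon_change: tuple[str, str] = ("TAT", "TAA")
    scan_window: int = 200
    flank: int = 12
    seed: int = 20240917

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("introns need >= 4 nt (GT...AG)")
        if sum(self.exon_lengths) % 3:
            raise ValueError("total exonic length must be a multiple of 3")


_SAFE = "C"  # stop codons contain no C, so all-C stretches are stop-proof


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    """Random sense codons, excluding ATG/stop bookends handled by caller."""
    pool = [c for c in SENSE_CODONS if c not in ("ATG",)]
    return [pool[i] for i in rng.integers(0, len(pool), size=n_codons)]


def _build_gene(spec: FixtureSpec, cds: str) -> tuple[str, GeneModel]:
    """Lay out exons/introns on a + strand genome with short flanks."""
    introns = []
    rng = np.random.default_rng(spec.seed + 1)
    for L in spec.intron_lengths:
        body = "".join("CA"[(i + 1) % 2] for i in range(L - 4))
        introns.append("GT" + body + "AG")
    flank = ("AC" * spec.flank)[: spec.flank]
    genome_parts = [flank]
    exons = []
    pos = len(flank)
    offset = 0
    for i, L in enumerate(spec.exon_lengths):
        exon_seq = cds[offset : offset + L]
        offset += L
        genome_parts.append(exon_seq)
        exons.append((pos, pos + L))
        pos += L
        if i < len(introns):
            genome_parts.append(introns[i])
            pos += len(introns[i])
    genome_parts.append(flank)
    genome = "".join(genome_parts)
    model = GeneModel(
        gene_id="fixture", strand="+", exons=tuple(exons), cds_start=0
    )
    return genome, model


def _assert_single_gt(window_seq: str, expect: int) -> None:
    hits = [
        i for i in range(len(window_seq) - 1) if window_seq[i : i + 2] == "GT"
    ]
    if hits != [expect]:
        raise ValueError(
            "cannot place a unique GT donor in the scan window "
            f"(found at offsets {hits}, wanted [{expect}])"
        )


def make_splice_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[str, GeneModel, list[Variant]]:
    """Construct the splice-donor fixture (mitfa archetype).

    The genome carries a multi-exon gene whose CDS spans the whole
    transcript (ATG … stop); canonical introns begin GT and end AG.  The
    affected exon's scanned suffix is built from C/A codons so that it
    contains exactly one GT dinucleotide, placed ``alt_donor_offset`` nt
    from the exon's 3′ end.  The returned variant replaces the reference
    span across the affected 5′ splice site (default CGG → TATATA,
    covering the exon's last two nt plus the first intronic G), which
    destroys the canonical GT donor.

    Raises ``ValueError`` when the requested offset makes a unique GT
    impossible (offsets 1 and 2).
    """
    spec = spec if spec is not None else FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    n_codons = sum(spec.exon_lengths) // 3
    codons = _random_cds(n_codons - 2, rng)
    cds = "ATG" + "".join(codons) + "TAA"

    # transcript coordinates of the affected exon
    ex_end = sum(spec.exon_lengths[: spec.splice_intron_index + 1])
    ex_start = ex_end - spec.exon_lengths[spec.splice_intron_index]
    if spec.splice_intron_index >= len(spec.intron_lengths):
        raise ValueError("splice_intron_index must name an internal intron")
    off = spec.alt_donor_offset
    if off >= spec.exon_lengths[spec.splice_intron_index]:
        raise ValueError("alt_donor_offset must fall inside the affected exon")
    if off in (1, 2):
        raise ValueError(
            "impossible to place a unique GT donor at offset 1 or 2"
        )

    # rebuild the exon's scanned suffix from stop-proof C/A filler
    window = min(spec.scan_window, spec.exon_lengths[spec.splice_intron_index])
    suffix = ["CA"[i % 2] for i in range(window)]

    def put(rel_from_end: int, s: str) -> None:
        # rel_from_end: distance of the string start from the exon 3' end
        start = window - rel_from_end
        suffix[start : start + len(s)] = list(s)

    put(2, "CG")  # exon ends ...CG so the CGG variant spans the junction
    if off == 3:
        # the canonical GT survives as context; the replacement's leading
        # TA turns the pre-placed G at -3 into a new GT donor post-edit
        put(3, "G")
    else:
        put(off, "GT")
    cds = cds[: ex_end - window] + "".join(suffix) + cds[ex_end:]

    # no stop codons may have been created in frame
    for k in range(0, len(cds) - 2, 3):
        if cds[k : k + 3] in STOP_CODONS and k != len(cds) - 3:
            raise AssertionError(f"internal stop created at codon {k // 3}")

    genome, model = _build_gene(spec, cds)

    ref, alt = spec.donor_replacement
    exon_g = model.exons[spec.splice_intron_index]
    var_pos = exon_g[1] - 2  # last two exonic nt + first intronic nt
    if genome[var_pos : var_pos + len(ref)] != ref:
        raise AssertionError(
            f"fixture reference mismatch at donor: "
            f"{genome[var_pos:var_pos + len(ref)]!r} != {ref!r}"
        )
    if off != 3:
        _assert_single_gt("".join(suffix[:-1]), window - off)
    variants = [Variant(position=var_pos, ref=ref, alt=alt)]
    return genome, model, variants


def make_ptc_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[str, GeneModel, list[Variant]]:
    """Construct the premature-stop fixture (tyrp1a archetype).

    A clean multi-exon gene in which one codon of ``ptc_exon_index`` is
    set to the reference triplet of ``ptc_codon_change`` (default TAT);
    the returned variant is the single T→A change that turns it into a
    stop.  The unmutated transcript translates without internal stops.
    """
    spec = spec if spec is not None else tyrp1a_fixture_spec()
    if spec.ptc_exon_index >= len(spec.exon_lengths):
        raise ValueError("ptc_exon_index out of range")
    ref_codon, alt_codon = spec.ptc_codon_change
    diffs = [p for p in range(3) if ref_codon[p] != alt_codon[p]]
    if len(diffs) != 1 or alt_codon not in STOP_CODONS:
        raise ValueError(
            "ptc_codon_change must turn a sense codon into a stop by one change"
        )
    (mut_pos_in_codon,) = diffs

    rng = np.random.default_rng(spec.seed)
    n_codons = sum(spec.exon_lengths) // 3
    codons = _random_cds(n_codons - 2, rng)
    cds = "ATG" + "".join(codons) + "TAA"

    ex_start = sum(spec.exon_lengths[: spec.ptc_exon_index])
    ex_len = spec.exon_lengths[spec.ptc_exon_index]
    # centre the target codon in the exon, on a codon boundary
    codon_tx = ((ex_start + ex_len // 2) // 3) * 3
    if codon_tx < ex_start or codon_tx + 3 > ex_start + ex_len:
        raise ValueError("affected exon too short to hold the target codon")
    if codon_tx == 0 or codon_tx == len(cds) - 3:
        raise ValueError("target codon collides with start/terminal codon")
    cds = cds[:codon_tx] + ref_codon + cds[codon_tx + 3 :]

    genome, model = _build_gene(spec, cds)
    genomic = model.transcript_to_genomic(codon_tx + mut_pos_in_codon)
    variant = Variant(
        position=genomic,
        ref=ref_codon[mut_pos_in_codon],
        alt=alt_codon[mut_pos_in_codon],
    )
    if genome[genomic] != variant.ref:
        raise AssertionError("fixture reference mismatch at PTC site")
    return genome, model, [variant]


def tyrp1a_fixture_spec(ptc_exon_index: int = 5) -> FixtureSpec:
    """Eight-exon layout for the premature-stop archetype."""
    return FixtureSpec(
        exon_lengths=(90, 120, 96, 150, 108, 135, 120, 99),
        intron_lengths=(80, 76, 84, 88, 92, 78, 86),
        ptc_exon_index=ptc_exon_index,
    )


def mitfa_like_fixture() -> tuple[str, GeneModel, list[Variant]]:
    """The packaged default splice fixture: CGG→TATATA at intron 4's
    donor, single alternative GT 63 nt upstream in exon 4."""
    return make_splice_fixture(FixtureSpec())


def tyrp1a_like_fixture(
    ptc_exon_index: int = 5,
) -> tuple[str, GeneModel, list[Variant]]:
    """The packaged default PTC fixture: T→A stop in exon 6 of 8."""
    return make_ptc_fixture(tyrp1a_fixture_spec(ptc_exon_index))
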