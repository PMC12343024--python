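"""Ka/Ks estimation from codon alignments.

Two estimators are provided for the fixed three-taxon (cave, surface,
outgroup) comparison:

* ``ka_ks_ng86`` — the Nei–Gojobori (1986) counting method on a pair of
  sequences, with pathway averaging over multi-hit codons and the
  Jukes–Cantor multiple-hit correction.
* ``fit_branch_model`` — maximum-likelihood estimation under a
  Goldman–Yang-style codon substitution model with one ω per labelled
  branch, the "branch model" used to contrast selective pressure on the
  cave and surface lineages.

Branch lengths are measured in expected substitutions per codon at
equilibrium.  ω (= Ka/Ks = dN/dS) below one indicates purifying
selection; ω near one indicates (nearly) neutral evolution.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm as scipy_expm
from scipy.optimize import minimize

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonAlignment",
    "TreeSpec",
    "GY94Params",
    "OmegaEstimate",
    "count_sites_ng86",
    "count_diffs_ng86",
    "ka_ks_ng86",
    "ng86_branch_estimates",
    "empirical_codon_freqs",
    "gy94_rate_matrix",
    "transition_matrix",
    "log_likelihood",
    "fit_branch_model",
    "branch_length_from_time",
    "BRANCH_NAMES",
]

BASES = "TCAG"
TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

# Standard nuclear genetic code (NCBI table 1), hard-coded: both loaches
# and the zebrafish outgroup are teleosts using the standard code.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

BRANCH_NAMES = ("cave", "surface", "outgroup")


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in TRANSITION_PAIRS


def _structural_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(one_diff, transition, nonsyn) boolean 61x61 matrices, cached."""
    one = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts = np.zeros_like(one)
    ns = np.zeros_like(one)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            one[i, j] = True
            ts[i, j] = _is_transition(*diffs[0])
            ns[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return one, ts, ns


_ONE_DIFF, _IS_TS, _IS_NONSYN = _structural_masks()


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """A gapless codon alignment over named taxa.

    ``sites[k]`` is the tuple of codons at alignment column ``k`` in taxon
    order.  Constructed via :meth:`from_sequences` from plain nucleotide
    strings (length divisible by 3).
    """

    taxa: tuple[str, ...]
    sites: tuple[tuple[str, ...], ...]
    source_id: str = ""

    @classmethod
    def from_sequences(
        cls, taxa, sequences, source_id: str = "", clean: bool = True
    ) -> "CodonAlignment":
        """Build from per-taxon nucleotide strings.

        With ``clean=True`` (default) codon columns containing gaps,
        ambiguity characters, or stop codons in any taxon are dropped
        silently; use :func:`clean_columns` when the drop count matters.
        """
        taxa = tuple(taxa)
        seqs = [str(s).upper().replace("U", "T") for s in sequences]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"sequence length {length} not divisible by 3")
        cols = []
        for k in range(0, length, 3):
            col = tuple(s[k : k + 3] for s in seqs)
            if clean and any(c not in CODON_INDEX for c in col):
                continue
            cols.append(col)
        return cls(taxa=taxa, sites=tuple(cols), source_id=source_id)

    @property
    def n_codons(self) -> int:
        return len(self.sites)

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(col[i] for col in self.sites)

    def indices(self) -> np.ndarray:
        """Integer codon indices, shape (n_taxa, n_codons)."""
        out = np.empty((len(self.taxa), len(self.sites)), dtype=np.int64)
        for k, col in enumerate(self.sites):
            for t, codon in enumerate(col):
                try:
                    out[t, k] = CODON_INDEX[codon]
                except KeyError:
                    raise ValueError(
                        f"non-sense codon {codon!r} at site {k}"
                    ) from None
        return out


def clean_columns(taxa, sequences, source_id: str = ""):
    """Like ``CodonAlignment.from_sequences`` but also report drop counts.

    Returns ``(alignment, n_dropped)``.
    """
    raw = CodonAlignment.from_sequences(taxa, sequences, source_id, clean=False)
    kept = tuple(
        col for col in raw.sites if all(c in CODON_INDEX for c in col)
    )
    n_dropped = len(raw.sites) - len(kept)
    return CodonAlignment(taxa=raw.taxa, sites=kept, source_id=source_id), n_dropped


@dataclass(frozen=True)
class TreeSpec:
    """The fixed unrooted 3-taxon star tree.

    Taxon names double as branch names; ``branch_labels`` maps each branch
    to an ω-class label (branches sharing a label share ω in the ML fit).
    """

    branch_lengths: dict[str, float]
    branch_labels: dict[str, str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.branch_labels is None:
            object.__setattr__(
                self, "branch_labels", {b: b for b in self.branch_lengths}
            )
        if set(self.branch_lengths) != set(BRANCH_NAMES):
            raise ValueError(
                f"tree must have exactly the branches {BRANCH_NAMES}"
            )
        if any(l < 0 for l in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")
        if set(self.branch_labels) != set(BRANCH_NAMES):
            raise ValueError("branch_labels must cover all three branches")

    @property
    def taxa(self) -> tuple[str, ...]:
        return BRANCH_NAMES


@dataclass(frozen=True)
class GY94Params:
    """Goldman–Yang codon-model parameters: κ, per-class ω, and π."""

    kappa: float
    omegas: dict[str, float]
    codon_freqs: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.codon_freqs, dtype=float)
        object.__setattr__(self, "codon_freqs", freqs)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if freqs.shape != (N_SENSE,):
            raise ValueError(f"codon_freqs must have length {N_SENSE}")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon_freqs must sum to 1")
        if any(w < 0 for w in self.omegas.values()):
            raise ValueError("omega must be >= 0")


@dataclass(frozen=True)
class OmegaEstimate:
    """Ka, Ks and ω for one gene x branch (or sequence pair).

    ``omega`` is ``None`` when undefined (Ks = 0, or a saturated
    Jukes–Cantor correction); the reason is recorded in ``notes``.
    """

    ka: float
    ks: float
    omega: float | None
    method: str
    lnl: float | None = None
    converged: bool = True
    notes: tuple[str, ...] = ()

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes (number of synonymous single-nucleotide
    neighbours)/3 synonymous sites; changes to stop codons count as
    nonsynonymous.  The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[neighbour] == aa:  # stops never match a sense aa
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _pathway_steps(ca: str, cb: str):
    """All single-step pathways from codon ``ca`` to ``cb``.

    Yields lists of (from_codon, to_codon) steps; pathways passing through
    stop codons are excluded.
    """
    diff_positions = [p for p in range(3) if ca[p] != cb[p]]
    for order in itertools.permutations(diff_positions):
        path = []
        cur = ca
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            path.append((cur, nxt))
            cur = nxt
        if ok:
            yield path


@functools.lru_cache(maxsize=None)
def count_diffs_ng86(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts for a codon pair.

    Multi-hit codons average over all orderings of single-nucleotide
    steps, excluding pathways through stop codons.  Raises ``ValueError``
    when every pathway is blocked (the caller skips and logs such pairs).
    """
    for c in (ca, cb):
        if c not in CODON_INDEX:
            raise ValueError(f"not a sense codon: {c!r}")
    if ca == cb:
        return 0.0, 0.0
    syn_counts = []
    nonsyn_counts = []
    for path in _pathway_steps(ca, cb):
        s = sum(1 for a, b in path if GENETIC_CODE[a] == GENETIC_CODE[b])
        syn_counts.append(float(s))
        nonsyn_counts.append(float(len(path) - s))
    if not syn_counts:
        raise ValueError(f"all pathways {ca}->{cb} pass through stop codons")
    return (
        sum(syn_counts) / len(syn_counts),
        sum(nonsyn_counts) / len(nonsyn_counts),
    )


def _jukes_cantor(p: float) -> float:
    # d = -(3/4) ln(1 - 4p/3); saturates (undefined) at p >= 0.75
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 0.75: JC correction saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ka_ks_ng86(seq_a, seq_b, source_id: str = "") -> OmegaEstimate:
    """NG86 Ka/Ks for a pair of codon sequences.

    Accepts nucleotide strings (length divisible by 3) or iterables of
    codons.  Site counts are averaged over the two sequences; codon pairs
    whose every mutational pathway crosses a stop codon are skipped (and
    noted).  ω is undefined when Ks = 0 or either Jukes–Cantor correction
    saturates.
    """
    codons_a = _as_codons(seq_a)
    codons_b = _as_codons(seq_b)
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences differ in codon length")
    if not codons_a:
        raise ValueError("zero-length input")
    notes: list[str] = []
    S = N = sd = nd = 0.0
    skipped = 0
    for ca, cb in zip(codons_a, codons_b):
        try:
            dsyn, dnon = count_diffs_ng86(ca, cb)
        except ValueError:
            skipped += 1
            continue
        sa, na = count_sites_ng86(ca)
        sb, nb = count_sites_ng86(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd += dsyn
        nd += dnon
    if skipped:
        notes.append(f"skipped {skipped} codon pairs with stop-blocked pathways")
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    try:
        ks = _jukes_cantor(ps)
    except ValueError:
        return OmegaEstimate(
            ka=math.nan, ks=math.nan, omega=None, method="NG86",
            notes=tuple(notes + ["Ks saturated (ps >= 0.75)"]),
        )
    try:
        ka = _jukes_cantor(pn)
    except ValueError:
        return OmegaEstimate(
            ka=math.nan, ks=ks, omega=None, method="NG86",
            notes=tuple(notes + ["Ka saturated (pn >= 0.75)"]),
        )
    if ks <= 0.0:
        notes.append("omega undefined: Ks = 0")
        omega = None
    else:
        omega = ka / ks
    return OmegaEstimate(ka=ka, ks=ks, omega=omega, method="NG86", notes=tuple(notes))


def _as_codons(seq) -> list[str]:
    if isinstance(seq, str):
        s = seq.upper().replace("U", "T")
        if len(s) % 3:
            raise ValueError("nucleotide string length not divisible by 3")
        return [s[i : i + 3] for i in range(0, len(s), 3)]
    return [str(c).upper() for c in seq]


def ng86_branch_estimates(alignment: CodonAlignment) -> dict[str, OmegaEstimate]:
    """Per-branch NG86 Ka/Ks via relative-rate decomposition.

    For the three-taxon star, pairwise distances decompose additively:
    the cave-branch distance is (d(cave,surface) + d(cave,outgroup) −
    d(surface,outgroup))/2, separately for Ka and Ks.  Negative values
    from sampling noise are clamped to 0.  Fast counting-based analogue
    of the ML branch model; used for summaries and as optimizer starts.
    """
    seqs = {t: alignment.sequence(t) for t in alignment.taxa}
    need = set(BRANCH_NAMES)
    if not need.issubset(seqs):
        raise ValueError(f"alignment must contain taxa {BRANCH_NAMES}")
    pair = {}
    for a, b in itertools.combinations(BRANCH_NAMES, 2):
        pair[frozenset((a, b))] = ka_ks_ng86(seqs[a], seqs[b])
    out: dict[str, OmegaEstimate] = {}
    for focal in BRANCH_NAMES:
        others = [b for b in BRANCH_NAMES if b != focal]
        d_near = [pair[frozenset((focal, o))] for o in others]
        d_far = pair[frozenset(tuple(others))]
        ests = d_near + [d_far]
        if any(not math.isfinite(e.ka) or not math.isfinite(e.ks) for e in ests):
            out[focal] = OmegaEstimate(
                ka=math.nan, ks=math.nan, omega=None, method="NG86",
                notes=("pairwise distance saturated",),
            )
            continue
        ka = max(0.0, 0.5 * (d_near[0].ka + d_near[1].ka - d_far.ka))
        ks = max(0.0, 0.5 * (d_near[0].ks + d_near[1].ks - d_far.ks))
        notes: tuple[str, ...] = ()
        if ks <= 0.0:
            omega = None
            notes = ("omega undefined: branch Ks = 0",)
        else:
            omega = ka / ks
        out[focal] = OmegaEstimate(ka=ka, ks=ks, omega=omega, method="NG86", notes=notes)
    return out


# ---------------------------------------------------------------------------
# GY94 branch model
# ---------------------------------------------------------------------------


def empirical_codon_freqs(alignment: CodonAlignment, model: str = "F3x4") -> np.ndarray:
    """Empirical codon frequencies over the 61 sense codons.

    ``model='F3x4'`` builds codon frequencies from the empirical
    nucleotide frequencies at each codon position (renormalized over
    sense codons); ``'empirical'`` uses raw codon counts with a +1
    pseudocount; ``'uniform'`` returns the flat distribution.
    """
    if model == "uniform":
        return np.full(N_SENSE, 1.0 / N_SENSE)
    idx = alignment.indices()
    if model == "empirical":
        counts = np.bincount(idx.ravel(), minlength=N_SENSE).astype(float) + 1.0
        return counts / counts.sum()
    if model != "F3x4":
        raise ValueError(f"unknown frequency model {model!r}")
    pos_freqs = np.zeros((3, 4))
    base_index = {b: i for i, b in enumerate(BASES)}
    for col in alignment.sites:
        for codon in col:
            for p, b in enumerate(codon):
                pos_freqs[p, base_index[b]] += 1.0
    pos_freqs += 1.0  # pseudocount keeps every sense codon reachable
    pos_freqs /= pos_freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, base_index[c[0]]]
            * pos_freqs[1, base_index[c[1]]]
            * pos_freqs[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _unscaled_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    Q = np.where(_ONE_DIFF, pi[None, :], 0.0)
    Q = Q * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def rate_flows(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution flow per unit time, unscaled."""
    Q = _unscaled_generator(kappa, omega, pi)
    off = np.where(_ONE_DIFF, pi[:, None] * Q, 0.0)
    syn = off[_ONE_DIFF & ~_IS_NONSYN].sum()
    nonsyn = off[_ONE_DIFF & _IS_NONSYN].sum()
    return float(syn), float(nonsyn)


def gy94_rate_matrix(params: GY94Params, omega_class: str) -> np.ndarray:
    """Scaled GY94 generator for one ω class.

    Off-diagonal entries are π_j · κ^[transition] · ω^[nonsynonymous] for
    single-nucleotide neighbours, 0 otherwise; the matrix is rescaled so
    the expected substitution rate at equilibrium is 1 (branch lengths
    are expected substitutions per codon).
    """
    if omega_class not in params.omegas:
        raise KeyError(f"unknown omega class {omega_class!r}")
    omega = params.omegas[omega_class]
    pi = params.codon_freqs
    Q = _unscaled_generator(params.kappa, omega, pi)
    rho = -float(pi @ np.diag(Q))
    if rho <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / rho


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) by scaling-and-squaring (Padé).

    Preferred over reconstruction from the π-symmetrized
    eigendecomposition: the latter only controls *absolute* error, so
    the tiny transition probabilities of short branches (which dominate
    some site likelihoods) lose relative accuracy.  Tiny negative
    entries from round-off are clamped to 0.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    P = scipy_expm(Q * t)
    np.maximum(P, 0.0, out=P)
    return P


def _site_patterns(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress columns of an index matrix into unique patterns + counts."""
    key = idx[0] * (N_SENSE * N_SENSE) + idx[1] * N_SENSE + idx[2]
    uniq, counts = np.unique(key, return_counts=True)
    pats = np.stack(
        [uniq // (N_SENSE * N_SENSE), (uniq // N_SENSE) % N_SENSE, uniq % N_SENSE]
    )
    return pats, counts


def _pattern_lnl(
    pats: np.ndarray,
    counts: np.ndarray,
    params: GY94Params,
    tree: TreeSpec,
    order: tuple[str, ...] = BRANCH_NAMES,
) -> float:
    pi = params.codon_freqs
    Qs = {lab: gy94_rate_matrix(params, lab) for lab in set(tree.branch_labels.values())}
    like = pi.copy()[:, None] * np.ones((1, pats.shape[1]))
    for t_i, branch in enumerate(order):
        P = transition_matrix(
            Qs[tree.branch_labels[branch]], tree.branch_lengths[branch], pi
        )
        like = like * P[:, pats[t_i]]
    site_l = like.sum(axis=0)
    if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
        bad = int(np.argmin(site_l))
        raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
    return float(counts @ np.log(site_l))


def log_likelihood(
    alignment: CodonAlignment, tree: TreeSpec, params: GY94Params
) -> float:
    """Log-likelihood of the alignment under the branch model.

    Felsenstein pruning on the 3-taxon star: per site,
    ``Σ_x π_x Π_b P_b(x → observed_b)``, with transition probabilities
    from the matrix exponential of each branch's scaled generator.
    """
    taxa = alignment.taxa
    if set(taxa) != set(BRANCH_NAMES):
        raise ValueError(f"alignment taxa {taxa} do not match tree {BRANCH_NAMES}")
    idx_raw = alignment.indices()
    order = tuple(BRANCH_NAMES)
    idx = np.stack([idx_raw[taxa.index(b)] for b in order])
    if idx.shape[1] == 0:
        return 0.0
    pats, counts = _site_patterns(idx)
    return _pattern_lnl(pats, counts, params, tree, order)


@dataclass
class BranchModelFit:
    """Result of :func:`fit_branch_model`."""

    params: GY94Params
    tree: TreeSpec
    estimates: dict[str, OmegaEstimate]
    lnl: float
    converged: bool
    n_starts: int = 0
    notes: tuple[str, ...] = ()


_KAPPA_BOUNDS = (0.1, 20.0)
_OMEGA_BOUNDS = (1e-4, 10.0)
_LENGTH_BOUNDS = (1e-6, 10.0)


def _ml_site_counts(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Per-codon synonymous/nonsynonymous site counts in the ML (mutational
    opportunity) sense: flows at ω = 1, normalized to 3 sites per codon."""
    syn1, non1 = rate_flows(kappa, 1.0, pi)
    tot = syn1 + non1
    return 3.0 * syn1 / tot, 3.0 * non1 / tot


def fit_branch_model(
    alignment: CodonAlignment,
    tree: TreeSpec,
    free_labels: set[str] | None = None,
    freq_model: str = "F3x4",
    n_starts: int = 3,
    seed: int = 0,
) -> BranchModelFit:
    """Maximum-likelihood branch-model fit on the 3-taxon star.

    Optimizes κ, the three branch lengths, and one ω per branch label in
    ``free_labels`` (default: all labels); codon frequencies are fixed at
    their empirical estimate (``freq_model``).  Bounded quasi-Newton
    (L-BFGS-B) in log-parameter space with ``n_starts`` starts: one
    informed by NG86 counting estimates, the rest randomly jittered
    (deterministically, via ``seed``).

    Returns per-branch :class:`OmegaEstimate` with model-based Ka/Ks:
    branch length times the model's class-conditional flow, divided by
    the mutational-opportunity site counts, so that Ka/Ks equals the
    fitted ω exactly.
    """
    labels = tuple(dict.fromkeys(tree.branch_labels[b] for b in BRANCH_NAMES))
    if free_labels is None:
        free = labels
    else:
        free = tuple(l for l in labels if l in free_labels)
    pi = empirical_codon_freqs(alignment, freq_model)

    taxa = alignment.taxa
    idx_raw = alignment.indices()
    order = tuple(BRANCH_NAMES)
    if set(taxa) != set(order):
        raise ValueError("alignment taxa must be cave/surface/outgroup")
    idx = np.stack([idx_raw[taxa.index(b)] for b in order])

    notes: list[str] = []
    if idx.shape[1] == 0 or bool(np.all(idx == idx[0:1, :])):
        # no variable sites: every length 0, omega unidentifiable
        params = GY94Params(
            kappa=2.0, omegas={l: 1.0 for l in labels}, codon_freqs=pi
        )
        ests = {
            b: OmegaEstimate(
                ka=0.0, ks=0.0, omega=None, method="ML", lnl=None,
                converged=False, notes=("no variable sites; all lengths 0",),
            )
            for b in BRANCH_NAMES
        }
        return BranchModelFit(
            params=params,
            tree=replace(tree, branch_lengths={b: 0.0 for b in BRANCH_NAMES}),
            estimates=ests,
            lnl=log_likelihood(alignment, tree, params) if idx.shape[1] else 0.0,
            converged=False,
            notes=("no variable sites",),
        )

    pats, counts = _site_patterns(idx)

    # NG86-informed start
    ng = ng86_branch_estimates(alignment)
    start_lengths = {}
    start_omegas = {l: 0.3 for l in labels}
    s3, n3 = _ml_site_counts(2.0, pi)
    for b in BRANCH_NAMES:
        e = ng[b]
        if math.isfinite(e.ka) and math.isfinite(e.ks):
            t0 = (e.ks * s3 + e.ka * n3) / 3.0 * 3.0  # subs per codon
            start_lengths[b] = min(max(t0, 1e-3), 5.0)
        else:
            start_lengths[b] = 0.3
    for l in labels:
        ws = [
            ng[b].omega
            for b in BRANCH_NAMES
            if tree.branch_labels[b] == l and ng[b].omega is not None
        ]
        if ws:
            start_omegas[l] = min(max(float(np.mean(ws)), 0.01), 5.0)

    def unpack(theta: np.ndarray) -> tuple[GY94Params, TreeSpec]:
        kappa = math.exp(theta[0])
        lengths = {b: math.exp(theta[1 + i]) for i, b in enumerate(BRANCH_NAMES)}
        omegas = dict(start_omegas)
        for i, l in enumerate(free):
            omegas[l] = math.exp(theta[4 + i])
        return (
            GY94Params(kappa=kappa, omegas=omegas, codon_freqs=pi),
            TreeSpec(branch_lengths=lengths, branch_labels=dict(tree.branch_labels)),
        )

    def neg_lnl(theta: np.ndarray) -> float:
        params_t, tree_t = unpack(theta)
        try:
            return -_pattern_lnl(pats, counts, params_t, tree_t, order)
        except FloatingPointError:
            return 1e12

    theta0 = np.array(
        [math.log(2.0)]
        + [math.log(start_lengths[b]) for b in BRANCH_NAMES]
        + [math.log(start_omegas[l]) for l in free]
    )
    bounds = (
        [tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_LENGTH_BOUNDS))] * 3
        + [tuple(np.log(_OMEGA_BOUNDS))] * len(free)
    )

    rng = np.random.default_rng(seed)
    best = None
    any_ok = False
    for s in range(max(1, n_starts)):
        theta_s = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, size=theta0.shape)
        theta_s = np.clip(
            theta_s, [b[0] for b in bounds], [b[1] for b in bounds]
        )
        res = minimize(
            neg_lnl,
            theta_s,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    converged = bool(any_ok and np.isfinite(best.fun))
    if not any_ok:
        notes.append("optimizer did not report convergence; best point returned")

    params_hat, tree_hat = unpack(best.x)
    lnl = -float(best.fun)

    s3, n3 = _ml_site_counts(params_hat.kappa, pi)
    syn1, non1 = rate_flows(params_hat.kappa, 1.0, pi)
    estimates: dict[str, OmegaEstimate] = {}
    for b in BRANCH_NAMES:
        w = params_hat.omegas[tree_hat.branch_labels[b]]
        t_b = tree_hat.branch_lengths[b]
        tot = syn1 + w * non1
        syn_subs = t_b * syn1 / tot  # per codon
        non_subs = t_b * w * non1 / tot
        # per-site rates: n3 (s3) nonsynonymous (synonymous) sites per codon
        estimates[b] = OmegaEstimate(
            ka=non_subs / n3, ks=syn_subs / s3, omega=w, method="ML",
            lnl=lnl, converged=converged,
        )
    return BranchModelFit(
        params=params_hat,
        tree=tree_hat,
        estimates=estimates,
        lnl=lnl,
        converged=converged,
        n_starts=max(1, n_starts),
        notes=tuple(notes),
    )


def branch_length_from_time(
    duration_my: float,
    omega: float,
    clock_rate: float,
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Convert a duration in My to a branch length (substitutions/codon).

    ``clock_rate`` is the synonymous substitution rate per codon per My,
    held constant across selective regimes; the total substitution rate
    then depends on ω through the nonsynonymous share of flow.
    """
    if clock_rate <= 0:
        raise ValueError("clock_rate must be > 0")
    if duration_my < 0:
        raise ValueError("duration must be >= 0")
    syn, nonsyn = rate_flows(kappa, omega, pi)
    # scale so synonymous subs/codon/My == clock_rate
    total_rate = clock_rate * (syn + nonsyn) / syn
    return duration_my * total_rate
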