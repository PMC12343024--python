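"""Transcript- and protein-level consequences of genomic variants.

Models the two mutation archetypes found in the cavefish pigmentation
genes:

* a 5′ splice-donor disruption rescued by an upstream in-exon GT donor
  (the *mitfa* event: donor replacement → 63-nt shorter transcript →
  21-aa in-frame deletion in the activation domain);
* a single-nucleotide change creating a premature termination codon
  (the *tyrp1a* event), followed by a nonsense-mediated-decay call via
  the classical 50-nt rule.

Coordinates are 0-based, half-open, on the + strand; minus-strand genes
are reverse-complement normalized at the GFF3 boundary (pipeline_io).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .codon_evolution import GENETIC_CODE

__all__ = [
    "GeneModel",
    "Variant",
    "SpliceOutcome",
    "ProteinConsequence",
    "apply_variants",
    "resplice",
    "translate_cds",
    "call_nmd",
    "protein_diff",
    "predict_consequences",
]


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene on the + strand.

    ``exons`` are (start, end) genomic intervals, 0-based half-open,
    non-overlapping, sorted 5′→3′; ``cds_start`` is the
    transcript-relative offset of the start codon.  Introns (the gaps
    between consecutive exons) must leave room for the GT…AG signals.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.cds_start < 0:
            raise ValueError("cds_start must be >= 0")
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
            if prev_end is not None:
                if s - prev_end < 4:
                    raise ValueError(
                        "introns need length >= 4 (room for GT...AG)"
                    )
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def transcript(self, genome: str) -> str:
        return "".join(genome[s:e] for s, e in self.exons)

    def transcript_to_genomic(self, tx_pos: int) -> int:
        """Map a transcript coordinate to its genomic position."""
        if tx_pos < 0:
            raise ValueError("transcript position must be >= 0")
        offset = tx_pos
        for s, e in self.exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
        raise ValueError(f"transcript position {tx_pos} beyond transcript end")


@dataclass(frozen=True)
class Variant:
    """A replacement edit: ``ref`` at ``position`` becomes ``alt``.

    Positions are 0-based genomic offsets on the reference genome (i.e.
    before any co-applied variant); lengths of ``ref`` and ``alt`` may
    differ.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class SpliceOutcome:
    """Result of assembling a transcript from a (possibly mutated) gene.

    ``donor_sites_used`` records, per intron, the genomic position of
    the donor actually used, its dinucleotide, and whether it is the
    canonical annotated one.  ``segment_lengths`` are the exonic segment
    lengths actually joined (needed for junction coordinates downstream).
    """

    transcript: str
    donor_sites_used: tuple[tuple[int, str, bool], ...]
    nt_delta: int
    rescue_applied: bool
    segment_lengths: tuple[int, ...]
    unresolved_introns: tuple[int, ...] = ()

    @property
    def resolved(self) -> bool:
        return not self.unresolved_introns


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level verdict for a variant's effect.

    ``kind`` is one of none / in_frame_deletion / frameshift /
    premature_stop / complex.  ``nmd_predicted`` is meaningful only for
    premature_stop.
    """

    kind: str
    aa_deleted: int = 0
    deletion_start: int | None = None
    ptc_codon_index: int | None = None
    nmd_predicted: bool | None = None
    distance_to_last_junction: int | None = None
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Variant application
# ---------------------------------------------------------------------------


def apply_variants(
    genome: str, gene_model: GeneModel, variants
) -> tuple[str, GeneModel]:
    """Apply non-overlapping replacement edits; remap gene coordinates.

    Every gene-model boundary strictly after an edited span shifts by
    that edit's length difference; a boundary inside an edited span
    keeps its offset from the span start (clamped to the replacement
    length), so an edit across an exon/intron junction leaves the exon
    the same length and rewrites the intron's first nucleotides.
    Variants are indexed on the input genome, so application order does
    not matter.
    """
    vs = sorted(variants, key=lambda v: v.position)
    for a, b in zip(vs, vs[1:]):
        if a.position + len(a.ref) > b.position:
            raise ValueError(
                f"overlapping variants at {a.position} and {b.position}"
            )
    for v in vs:
        observed = genome[v.position : v.position + len(v.ref)]
        if observed != v.ref:
            raise ValueError(
                f"reference mismatch at {v.position}: genome has "
                f"{observed!r}, variant expects {v.ref!r}"
            )

    def remap(pos: int) -> int:
        shift = 0
        for v in vs:
            span_end = v.position + len(v.ref)
            if pos >= span_end:
                shift += v.delta
            elif pos > v.position:
                # inside the span: keep the offset, clamped to the new span
                offset = min(pos - v.position, len(v.alt))
                return v.position + shift + offset
        return pos + shift

    pieces = []
    cursor = 0
    for v in vs:
        pieces.append(genome[cursor : v.position])
        pieces.append(v.alt)
        cursor = v.position + len(v.ref)
    pieces.append(genome[cursor:])
    mutated = "".join(pieces)

    new_exons = tuple((remap(s), remap(e)) for s, e in gene_model.exons)
    new_model = replace(gene_model, exons=new_exons)
    return mutated, new_model


# ---------------------------------------------------------------------------
# Splicing
# ---------------------------------------------------------------------------


def resplice(genome: str, gene_model: GeneModel, scan_window: int = 200) -> SpliceOutcome:
    """Assemble the mature transcript, rescuing broken 5′ donors.

    For each intron: if the first two intronic nucleotides are GT the
    canonical donor is used (GC is accepted but flagged non-canonical).
    Otherwise the upstream exon is scanned 3′→5′ within ``scan_window``
    nt for the nearest GT — failing that, the nearest GC — and the donor
    shifts there: the exonic suffix from the new donor onward joins the
    intron, shortening the transcript.  A GT at any distance beats a GC
    at any distance.  If no candidate exists the intron is retained in
    the transcript and flagged unresolved.

    Acceptors are assumed intact (acceptor mutations are out of scope);
    ``nt_delta`` is the signed length change versus the annotated
    transcript.
    """
    if scan_window < 2:
        raise ValueError("scan_window must be >= 2")
    exons = list(gene_model.exons)
    segments: list[tuple[int, int]] = []
    donors: list[tuple[int, str, bool]] = []
    unresolved: list[int] = []
    rescue = False
    retained: dict[int, tuple[int, int]] = {}

    for i, (s, e) in enumerate(exons):
        seg_end = e
        if i < len(exons) - 1:
            intron_start = e
            dinuc = genome[intron_start : intron_start + 2]
            if dinuc == "GT":
                donors.append((intron_start, dinuc, True))
            elif dinuc == "GC":
                donors.append((intron_start, dinuc, True))
            else:
                candidate = _scan_upstream_donor(genome, s, e, scan_window)
                if candidate is None:
                    # intron retention: keep the intron sequence
                    donors.append((intron_start, dinuc, False))
                    unresolved.append(i)
                    retained[i] = (e, exons[i + 1][0])
                else:
                    pos, found = candidate
                    donors.append((pos, found, False))
                    seg_end = pos
                    rescue = True
        segments.append((s, seg_end))

    parts = []
    seg_lengths = []
    for i, (s, e) in enumerate(segments):
        parts.append(genome[s:e])
        length = e - s
        if i in retained:
            rs, re = retained[i]
            parts.append(genome[rs:re])
            length += re - rs
        seg_lengths.append(length)
    transcript = "".join(parts)
    nt_delta = len(transcript) - gene_model.transcript_length()
    return SpliceOutcome(
        transcript=transcript,
        donor_sites_used=tuple(donors),
        nt_delta=nt_delta,
        rescue_applied=rescue,
        segment_lengths=tuple(seg_lengths),
        unresolved_introns=tuple(unresolved),
    )


def _scan_upstream_donor(
    genome: str, exon_start: int, exon_end: int, scan_window: int
) -> tuple[int, str] | None:
    """Nearest in-exon GT (preferred) or GC donor upstream of a broken site.

    Scans positions p with genome[p:p+2] fully inside the exon, from the
    3′ end towards 5′, at most ``scan_window`` nt from the exon end.
    """
    lo = max(exon_start, exon_end - scan_window)
    best_gc = None
    for p in range(exon_end - 2, lo - 1, -1):
        dinuc = genome[p : p + 2]
        if dinuc == "GT":
            return p, "GT"
        if dinuc == "GC" and best_gc is None:
            best_gc = (p, "GC")
    return best_gc


# ---------------------------------------------------------------------------
# Translation and NMD
# ---------------------------------------------------------------------------


def translate_cds(transcript: str, cds_start: int = 0) -> tuple[str, int | None]:
    """Translate from ``cds_start`` to the first stop codon.

    Returns (protein, stop_codon_index) where the index counts codons
    from ``cds_start``; ``None`` when no stop occurs before the end of
    the transcript (a "non-stop" transcript).  Trailing sub-codon
    nucleotides are ignored.
    """
    if not (0 <= cds_start <= len(transcript)):
        raise ValueError("cds_start outside transcript")
    protein = []
    k = cds_start
    codon_index = 0
    while k + 3 <= len(transcript):
        codon = transcript[k : k + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(f"unrecognized codon {codon!r} at {k}")
        if aa == "*":
            return "".join(protein), codon_index
        protein.append(aa)
        k += 3
        codon_index += 1
    return "".join(protein), None


def call_nmd(
    ptc_codon_index: int,
    cds_start: int,
    segment_lengths,
) -> tuple[bool, int]:
    """Apply the classical 50-nt rule to a premature stop.

    ``segment_lengths`` are the exonic segment lengths of the transcript
    as actually spliced.  The distance is counted from the PTC's last
    nucleotide to the final exon–exon junction, in transcript
    coordinates; decay is predicted when the PTC lies more than 50 nt
    upstream of that junction.  Single-exon transcripts are never NMD
    substrates.
    """
    segs = list(segment_lengths)
    if ptc_codon_index < 0:
        raise ValueError("ptc_codon_index must be >= 0")
    if len(segs) < 2:
        return False, 0
    last_junction = sum(segs[:-1])  # transcript coord where the final exon starts
    ptc_last_nt = cds_start + 3 * ptc_codon_index + 2
    distance = last_junction - (ptc_last_nt + 1)
    return distance > 50, distance


# ---------------------------------------------------------------------------
# Protein comparison
# ---------------------------------------------------------------------------


def protein_diff(
    ref_protein: str,
    alt_protein: str,
    nt_delta: int | None = None,
    ref_had_stop: bool = True,
    alt_had_stop: bool = True,
) -> ProteinConsequence:
    """Classify the difference between reference and mutant proteins.

    Categories: identical → ``none``; the mutant equals the reference
    with one contiguous block removed → ``in_frame_deletion``; the
    mutant is a strict prefix of the reference (early stop, frame
    intact) → ``premature_stop``; a shared prefix followed by divergent
    sequence with a frame-breaking ``nt_delta`` → ``frameshift``;
    anything else → ``complex``.
    """
    if not ref_protein or not alt_protein:
        raise ValueError("proteins must be non-empty")
    notes: list[str] = []
    if not alt_had_stop:
        notes.append("mutant transcript has no stop codon (non-stop)")
    if ref_protein == alt_protein:
        return ProteinConsequence(kind="none", notes=tuple(notes))

    frame_broken = nt_delta is not None and nt_delta % 3 != 0

    if (
        not frame_broken
        and len(alt_protein) < len(ref_protein)
        and ref_protein.startswith(alt_protein)
    ):
        return ProteinConsequence(
            kind="premature_stop",
            ptc_codon_index=len(alt_protein),
            notes=tuple(notes),
        )

    if not frame_broken and len(alt_protein) < len(ref_protein):
        k = len(ref_protein) - len(alt_protein)
        prefix = 0
        while (
            prefix < len(alt_protein)
            and ref_protein[prefix] == alt_protein[prefix]
        ):
            prefix += 1
        if ref_protein[:prefix] + ref_protein[prefix + k :] == alt_protein:
            return ProteinConsequence(
                kind="in_frame_deletion",
                aa_deleted=k,
                deletion_start=prefix,
                notes=tuple(notes),
            )

    if frame_broken:
        prefix = 0
        limit = min(len(ref_protein), len(alt_protein))
        while prefix < limit and ref_protein[prefix] == alt_protein[prefix]:
            prefix += 1
        return ProteinConsequence(
            kind="frameshift",
            deletion_start=prefix,
            ptc_codon_index=len(alt_protein) if alt_had_stop else None,
            notes=tuple(notes),
        )

    return ProteinConsequence(kind="complex", notes=tuple(notes))


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def predict_consequences(
    genome: str,
    gene_model: GeneModel,
    variants,
    scan_window: int = 200,
) -> tuple[SpliceOutcome, ProteinConsequence]:
    """Full pipeline: mutate → re-splice → translate → classify.

    The reference transcript comes from splicing the unmutated gene;
    premature stops are checked with the 50-nt NMD rule on the mutant's
    actual exon junction layout.
    """
    ref_splice = resplice(genome, gene_model, scan_window)
    ref_protein, ref_stop = translate_cds(
        ref_splice.transcript, gene_model.cds_start
    )
    mut_genome, mut_model = apply_variants(genome, gene_model, variants)
    mut_splice = resplice(mut_genome, mut_model, scan_window)
    mut_protein, mut_stop = translate_cds(
        mut_splice.transcript, mut_model.cds_start
    )
    if not variants and mut_splice.transcript == ref_splice.transcript:
        return mut_splice, ProteinConsequence(kind="none")
    consequence = protein_diff(
        ref_protein,
        mut_protein,
        nt_delta=mut_splice.nt_delta,
        alt_had_stop=mut_stop is not None,
    )
    if consequence.kind == "premature_stop":
        nmd, dist = call_nmd(
            consequence.ptc_codon_index,
            mut_model.cds_start,
            mut_splice.segment_lengths,
        )
        consequence = replace(
            consequence, nmd_predicted=nmd, distance_to_last_junction=dist
        )
    return mut_splice, consequence
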