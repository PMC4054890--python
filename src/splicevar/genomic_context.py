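"""Reference sequence, gene models and per-variant exon context.

All coordinates are 0-based half-open internally; 1-based inclusive
conventions (FASTA-adjacent formats, GTF, VCF) are converted at the I/O
boundary. All sequence-derived quantities are computed on the *sense*
strand of the selected transcript: loci on the minus strand are
reverse-complemented before any downstream feature sees them.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import gffutils
import pyfaidx

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGT")

#: standard genetic code, DNA alphabet, '*' = stop
CODON_TABLE = {}


def _init_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_init_codon_table()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed or internally inconsistent gene annotation."""


class VariantError(ValueError):
    """Variant fails validation against the reference."""


class NotExonicError(VariantError):
    """Variant does not fall inside any annotated exon (exclusion signal)."""


@dataclass(frozen=True)
class GenomeSequence:
    """In-memory reference: contig id -> upper-case A/C/G/T/N string."""

    contigs: dict

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty contig {name!r}")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return [start, end) on the requested strand (minus = revcomp)."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval [{start},{end}) outside contig {contig} "
                f"of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)


def load_genome(fasta_path) -> GenomeSequence:
    """Load a FASTA reference, upper-casing and validating the alphabet.

    IUPAC ambiguity codes other than N are rejected: downstream hexamer
    and k-mer features are only defined over {A,C,G,T,N}.
    """
    fa = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    contigs = {}
    allowed = VALID_BASES | {"N"}
    for name in fa.keys():
        seq = str(fa[name][:])
        if not seq:
            raise ValueError(f"empty FASTA record {name!r}")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"contig {name!r} contains disallowed characters {sorted(bad)}"
            )
        contigs[name] = seq
    if not contigs:
        raise ValueError(f"no records in {fasta_path}")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS extent.

    ``exons`` are genomic 0-based half-open intervals sorted by start;
    ``cds_start``/``cds_end`` delimit the genomic CDS span (half-open) or
    are None for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple
    cds_start: int = None
    cds_end: int = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e - s < 1:
                raise AnnotationError(
                    f"zero-length exon [{s},{e}) in {self.transcript_id}"
                )
            if s < prev_end:
                raise AnnotationError(
                    f"overlapping/unsorted exons in {self.transcript_id}"
                )
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_containing(self, pos: int):
        """Genomic-order index of the exon containing ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        return None

    def coding_exon_indices(self):
        """Genomic-order indices of exons overlapping the CDS."""
        if self.cds_start is None:
            return []
        return [
            i
            for i, (s, e) in enumerate(self.exons)
            if s < self.cds_end and e > self.cds_start
        ]


@dataclass
class GeneModels:
    """All transcripts of an annotation, grouped by gene."""

    transcripts: dict = field(default_factory=dict)
    by_gene: dict = field(default_factory=dict)

    def add(self, tx: TranscriptModel) -> None:
        self.transcripts[tx.transcript_id] = tx
        self.by_gene.setdefault(tx.gene_id, []).append(tx.transcript_id)

    def gene_transcripts(self, gene_id: str):
        return [self.transcripts[t] for t in self.by_gene[gene_id]]

    def transcript_number(self, gene_id: str) -> int:
        return len(self.by_gene[gene_id])

    def is_constitutive(self, tx: TranscriptModel, exon_idx: int) -> bool:
        """True when the exon's genomic interval occurs in every transcript
        of its gene (identical-interval semantics)."""
        interval = tx.exons[exon_idx]
        return all(
            interval in other.exons for other in self.gene_transcripts(tx.gene_id)
        )

    def transcripts_overlapping(self, contig: str, pos: int):
        out = []
        for tx in self.transcripts.values():
            if tx.contig == contig and tx.exon_containing(pos) is not None:
                out.append(tx)
        return out

    def donor_junctions(self):
        """Set of (contig, genomic position of first intronic base) for all
        annotated exon->intron junctions, both strands in genomic coords."""
        out = set()
        for tx in self.transcripts.values():
            for i, (s, e) in enumerate(tx.exons):
                last = i == len(tx.exons) - 1
                first = i == 0
                if tx.strand == "+":
                    if not last:
                        out.add((tx.contig, e))
                else:
                    if not first:
                        out.add((tx.contig, s - 1))
        return out


def load_annotation(gtf_path) -> GeneModels:
    """Parse a GTF/GFF3 into TranscriptModels (via gffutils, in memory).

    Requires exon features carrying transcript_id and gene_id attributes;
    CDS features are optional. GTF 1-based inclusive coordinates become
    0-based half-open here.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons = defaultdict(list)
    meta = {}
    cds = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        meta[tid] = (gid, f.seqid, f.strand)
        exons[tid].append((f.start - 1, f.end))
    for f in db.features_of_type("CDS"):
        tid = f.attributes["transcript_id"][0]
        lo, hi = cds.get(tid, (f.start - 1, f.end))
        cds[tid] = (min(lo, f.start - 1), max(hi, f.end))
    if not exons:
        raise AnnotationError(f"no exon features in {gtf_path}")
    models = GeneModels()
    for tid, ivals in exons.items():
        gid, contig, strand = meta[tid]
        c0, c1 = cds.get(tid, (None, None))
        models.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=tuple(sorted(ivals)),
                cds_start=c0,
                cds_end=c1,
            )
        )
    return models


@dataclass(frozen=True)
class Variant:
    """A single-base substitution, reference-strand alleles, 0-based pos."""

    contig: str
    pos: int
    ref: str
    alt: str
    variant_id: str = ""
    label: str = None  # SAV / SNV / None (unlabeled)
    coding_effect: str = None

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise VariantError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise VariantError("ref and alt alleles identical")

    @property
    def name(self) -> str:
        return self.variant_id or f"{self.contig}:{self.pos + 1}{self.ref}>{self.alt}"


def validate_variant(variant: Variant, genome: GenomeSequence) -> None:
    actual = genome.base(variant.contig, variant.pos)
    if actual != variant.ref:
        raise VariantError(
            f"{variant.name}: reference is {actual}, variant claims {variant.ref}"
        )


@dataclass
class ExonContext:
    """A variant anchored to its target exon, everything sense-strand.

    ``offset`` is the variant's position within ``exon_seq``; intronic
    flanks are up to ``flank`` bases adjacent to the exon (upstream =
    acceptor side, downstream = donor side in transcription order).
    """

    variant: Variant
    transcript: TranscriptModel
    exon_genomic_index: int
    exon_index: int  # transcription order, 0-based
    exon_seq: str
    offset: int
    ref: str  # sense-strand alleles
    alt: str
    upstream_intron_seq: str
    downstream_intron_seq: str
    upstream_intron_len: int
    downstream_intron_len: int
    has_upstream: bool
    has_downstream: bool
    truncated_upstream: bool
    truncated_downstream: bool
    internal_coding_exon: bool
    constitutive_exon: bool
    transcript_number: int

    @property
    def exon_len(self) -> int:
        return len(self.exon_seq)

    @property
    def n_exons(self) -> int:
        return self.transcript.n_exons

    def region(self):
        """(sequence, variant offset, exon start offset, exon end offset)
        for the flank+exon+flank sense-strand window."""
        up = self.upstream_intron_seq
        seq = up + self.exon_seq + self.downstream_intron_seq
        return seq, len(up) + self.offset, len(up), len(up) + self.exon_len

    def mutant_region(self):
        seq, off, a, b = self.region()
        return seq[:off] + self.alt + seq[off + 1 :], off, a, b


def resolve_context(
    variant: Variant,
    models: GeneModels,
    genome: GenomeSequence,
    flank: int = 100,
) -> ExonContext:
    """Anchor a variant to its target exon.

    Among transcripts whose exons contain the variant, the one with the
    most exons wins; ties break on lexicographic transcript id. Raises
    NotExonicError when no exon contains the variant.
    """
    validate_variant(variant, genome)
    hits = models.transcripts_overlapping(variant.contig, variant.pos)
    if not hits:
        raise NotExonicError(f"{variant.name}: not inside any annotated exon")
    tx = min(hits, key=lambda t: (-t.n_exons, t.transcript_id))
    gi = tx.exon_containing(variant.pos)
    s, e = tx.exons[gi]
    n = tx.n_exons
    minus = tx.strand == "-"
    exon_seq = genome.fetch(tx.contig, s, e, tx.strand)
    contig_len = genome.length(tx.contig)

    # genomic-left and genomic-right introns
    left_len = s - tx.exons[gi - 1][1] if gi > 0 else 0
    right_len = tx.exons[gi + 1][0] - e if gi < n - 1 else 0

    def left_flank(want):
        m = min(want, s)
        return genome.fetch(tx.contig, s - m, s), m < want

    def right_flank(want):
        m = min(want, contig_len - e)
        return genome.fetch(tx.contig, e, e + m), m < want

    if not minus:
        up_len, down_len = left_len, right_len
        up_seq, up_trunc = (
            left_flank(min(flank, left_len)) if gi > 0 else ("", False)
        )
        down_seq, down_trunc = (
            right_flank(min(flank, right_len)) if gi < n - 1 else ("", False)
        )
        offset = variant.pos - s
        ref_s, alt_s = variant.ref, variant.alt
        exon_index = gi
    else:
        up_len, down_len = right_len, left_len
        raw_up, up_trunc = (
            right_flank(min(flank, right_len)) if gi < n - 1 else ("", False)
        )
        raw_down, down_trunc = (
            left_flank(min(flank, left_len)) if gi > 0 else ("", False)
        )
        up_seq = reverse_complement(raw_up)
        down_seq = reverse_complement(raw_down)
        offset = (e - 1) - variant.pos
        ref_s = reverse_complement(variant.ref)
        alt_s = reverse_complement(variant.alt)
        exon_index = n - 1 - gi

    coding = tx.coding_exon_indices()
    internal_coding = bool(coding) and gi in coding and gi not in (
        min(coding),
        max(coding),
    )

    return ExonContext(
        variant=variant,
        transcript=tx,
        exon_genomic_index=gi,
        exon_index=exon_index,
        exon_seq=exon_seq,
        offset=offset,
        ref=ref_s,
        alt=alt_s,
        upstream_intron_seq=up_seq,
        downstream_intron_seq=down_seq,
        upstream_intron_len=up_len,
        downstream_intron_len=down_len,
        has_upstream=exon_index > 0,
        has_downstream=exon_index < n - 1,
        truncated_upstream=up_trunc,
        truncated_downstream=down_trunc,
        internal_coding_exon=internal_coding,
        constitutive_exon=models.is_constitutive(tx, gi),
        transcript_number=models.transcript_number(tx.gene_id),
    )


def distance_to_nearest_splice_site(context: ExonContext):
    """Distance (bp) from the variant to the closer exon boundary.

    The exon-terminal base has distance 0. Returns (distance, side) with
    side 'acceptor' (exon start, sense) or 'donor' (exon end); ties go to
    the donor side.
    """
    d_acc = context.offset
    d_don = context.exon_len - 1 - context.offset
    if d_don <= d_acc:
        return d_don, "donor"
    return d_acc, "acceptor"


def exon_gene_features(context: ExonContext) -> dict:
    """Exon- and gene-level fields of the feature schema.

    Absent intronic flanks (first/last exons) are reported as length 0
    alongside explicit has_upstream/has_downstream flags.
    """
    seq = context.exon_seq
    gc = 100.0 * sum(b in "GC" for b in seq) / len(seq)
    return {
        "exon_gc_pct": gc,
        "exon_size": context.exon_len,
        "upstream_intron_len": context.upstream_intron_len,
        "downstream_intron_len": context.downstream_intron_len,
        "has_upstream": context.has_upstream,
        "has_downstream": context.has_downstream,
        "internal_coding_exon": context.internal_coding_exon,
        "constitutive_exon": context.constitutive_exon,
        "exon_number": context.n_exons,
        "transcript_number": context.transcript_number,
    }


class NonCodingError(VariantError):
    """Variant lies in a transcript but outside its CDS."""


def classify_coding_effect(
    variant: Variant, tx: TranscriptModel, genome: GenomeSequence
) -> str:
    """Missense / same-sense / nonsense call under the standard code."""
    if tx.cds_start is None:
        raise NonCodingError(f"{tx.transcript_id} has no CDS")
    pieces = []
    pos_map = []  # genomic position per CDS base, genomic order
    for s, e in tx.exons:
        lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
        if lo < hi:
            pieces.append(genome.fetch(tx.contig, lo, hi))
            pos_map.extend(range(lo, hi))
    cds = "".join(pieces)
    if len(cds) % 3 != 0:
        raise AnnotationError(
            f"CDS length {len(cds)} of {tx.transcript_id} not divisible by 3"
        )
    try:
        idx = pos_map.index(variant.pos)
    except ValueError:
        raise NonCodingError(f"{variant.name}: outside CDS") from None
    if tx.strand == "-":
        cds = reverse_complement(cds)
        idx = len(cds) - 1 - idx
        ref_s, alt_s = (
            reverse_complement(variant.ref),
            reverse_complement(variant.alt),
        )
    else:
        ref_s, alt_s = variant.ref, variant.alt
    if cds[idx] != ref_s:
        raise VariantError(f"{variant.name}: CDS/reference mismatch")
    ci = idx // 3
    codon = cds[3 * ci : 3 * ci + 3]
    within = idx % 3
    mut_codon = codon[:within] + alt_s + codon[within + 1 :]
    aa_wt = CODON_TABLE[codon]
    aa_mut = CODON_TABLE[mut_codon]
    if aa_wt == aa_mut:
        return "same-sense"
    if aa_mut == "*":
        return "nonsense"
    return "missense"
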