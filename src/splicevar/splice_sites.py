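"""Splice-site strength scoring and cryptic-site scanning.

Window geometry follows the MaxEntScan convention: a donor (5') site is a
9-mer of 3 exonic + 6 intronic bases; an acceptor (3') site is a 23-mer of
20 intronic + 3 exonic bases. The scoring backend is pluggable — anything
with ``window_length`` and ``score(window) -> float`` works. Two backends
ship here: externally supplied score tables, and a position weight matrix
trained on the annotation's own junctions so the toolkit is self-contained
without genome-wide model downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_context import ExonContext, GeneModels, GenomeSequence

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
DONOR_LEN = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PwmScorer:
    """Log-odds position weight matrix: score = sum_i log2(p_i(b)/bg(b))."""

    kind: str  # 'donor' or 'acceptor'
    matrix: np.ndarray  # (window_length, 4)

    @property
    def window_length(self) -> int:
        return self.matrix.shape[0]

    def score(self, window: str) -> float:
        if len(window) != self.window_length:
            raise ValueError(
                f"{self.kind} window must be {self.window_length} bp, "
                f"got {len(window)}"
            )
        total = 0.0
        for i, b in enumerate(window):
            try:
                total += self.matrix[i, _BASE_IDX[b]]
            except KeyError:
                raise ValueError(f"invalid base {b!r} in window") from None
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list("ACGT"))

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_pwm_scorer(path, kind: str) -> PwmScorer:
    df = pd.read_csv(path, sep="\t")
    return PwmScorer(kind, df[list("ACGT")].to_numpy(dtype=float))


@dataclass(frozen=True)
class TableScorer:
    """Exact-lookup backend for externally supplied model tables.

    The TSV dialect is two columns, ``window`` and ``score``, one row per
    scored window; all windows must share one length.
    """

    kind: str
    scores: dict
    window_length: int

    def score(self, window: str) -> float:
        if len(window) != self.window_length:
            raise ValueError(f"window length {len(window)} != {self.window_length}")
        try:
            return self.scores[window]
        except KeyError:
            raise KeyError(f"window {window!r} not in score table") from None


def load_table_scorer(path, kind: str) -> TableScorer:
    df = pd.read_csv(path, sep="\t")
    lengths = df.window.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"inconsistent window lengths in {path}")
    return TableScorer(kind, dict(zip(df.window, df.score)), int(lengths[0]))


def train_pwm_scorer(
    sites, kind: str, pseudocount: float = 1.0, background=None
) -> PwmScorer:
    """Fit the log-odds PWM from aligned true-site windows.

    ``background`` is a length-4 base composition (default uniform).
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no training sites")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("training sites have inconsistent lengths")
    counts = np.full((length, 4), pseudocount, dtype=float)
    for s in sites:
        for i, b in enumerate(s):
            counts[i, _BASE_IDX[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PwmScorer(kind, np.log2(probs / bg))


def annotation_site_windows(genome: GenomeSequence, models: GeneModels):
    """Collect sense-strand donor 9-mers and acceptor 23-mers from every
    internal junction in the annotation (skipping windows that run off the
    contig)."""
    donors, acceptors = [], []
    for tx in models.transcripts.values():
        clen = genome.length(tx.contig)
        for gi, (s, e) in enumerate(tx.exons):
            plus = tx.strand == "+"
            # donor side: exon end in transcription order
            is_last = gi == tx.n_exons - 1 if plus else gi == 0
            is_first = gi == 0 if plus else gi == tx.n_exons - 1
            if not is_last:
                if plus:
                    a, b = e - DONOR_EXONIC, e + DONOR_INTRONIC
                else:
                    a, b = s - DONOR_INTRONIC, s + DONOR_EXONIC
                if 0 <= a and b <= clen:
                    donors.append(genome.fetch(tx.contig, a, b, tx.strand))
            if not is_first:
                if plus:
                    a, b = s - ACCEPTOR_INTRONIC, s + ACCEPTOR_EXONIC
                else:
                    a, b = e - ACCEPTOR_EXONIC, e + ACCEPTOR_INTRONIC
                if 0 <= a and b <= clen:
                    acceptors.append(genome.fetch(tx.contig, a, b, tx.strand))
    return donors, acceptors


def train_scorers_from_annotation(genome: GenomeSequence, models: GeneModels):
    donors, acceptors = annotation_site_windows(genome, models)
    return (
        train_pwm_scorer(donors, "donor"),
        train_pwm_scorer(acceptors, "acceptor"),
    )


@dataclass
class SiteStrengths:
    five_prime: float = None  # donor of the target exon
    three_prime: float = None  # acceptor of the target exon
    five_prime_absent: str = ""
    three_prime_absent: str = ""


def _donor_window(context: ExonContext, mutant: bool = False):
    """Wild-type or mutant donor 9-mer of the target exon, or None."""
    if not context.has_downstream or len(context.downstream_intron_seq) < DONOR_INTRONIC:
        return None
    exon = context.exon_seq
    if mutant and context.offset >= context.exon_len - DONOR_EXONIC:
        exon = exon[: context.offset] + context.alt + exon[context.offset + 1 :]
    if context.exon_len < DONOR_EXONIC:
        return None
    return exon[-DONOR_EXONIC:] + context.downstream_intron_seq[:DONOR_INTRONIC]


def _acceptor_window(context: ExonContext, mutant: bool = False):
    if not context.has_upstream or len(context.upstream_intron_seq) < ACCEPTOR_INTRONIC:
        return None
    exon = context.exon_seq
    if mutant and context.offset < ACCEPTOR_EXONIC:
        exon = exon[: context.offset] + context.alt + exon[context.offset + 1 :]
    if context.exon_len < ACCEPTOR_EXONIC:
        return None
    return context.upstream_intron_seq[-ACCEPTOR_INTRONIC:] + exon[:ACCEPTOR_EXONIC]


def natural_site_strength(
    context: ExonContext, donor_scorer, acceptor_scorer
) -> SiteStrengths:
    """Wild-type strengths of the target exon's own donor and acceptor.

    First/last exons (or flanks too short to form a window) yield a flagged
    absent score on the corresponding side.
    """
    out = SiteStrengths()
    dw = _donor_window(context)
    if dw is None:
        out.five_prime_absent = "no donor window"
    else:
        out.five_prime = donor_scorer.score(dw)
    aw = _acceptor_window(context)
    if aw is None:
        out.three_prime_absent = "no acceptor window"
    else:
        out.three_prime = acceptor_scorer.score(aw)
    return out


@dataclass
class DeltaResult:
    value: float
    in_donor: bool = False
    in_acceptor: bool = False
    both_windows: bool = False


def delta_natural_site(
    context: ExonContext, donor_scorer, acceptor_scorer
) -> DeltaResult:
    """Mutant-minus-wild-type strength of any natural site window the
    variant touches; 0 when it touches neither. A variant inside both
    windows (tiny exon) reports the larger-magnitude delta, flagged."""
    deltas = []
    in_donor = context.offset >= context.exon_len - DONOR_EXONIC
    in_acceptor = context.offset < ACCEPTOR_EXONIC
    if in_donor:
        wt, mut = _donor_window(context), _donor_window(context, mutant=True)
        if wt is not None:
            deltas.append(("donor", donor_scorer.score(mut) - donor_scorer.score(wt)))
    if in_acceptor:
        wt, mut = _acceptor_window(context), _acceptor_window(context, mutant=True)
        if wt is not None:
            deltas.append(
                ("acceptor", acceptor_scorer.score(mut) - acceptor_scorer.score(wt))
            )
    if not deltas:
        return DeltaResult(0.0)
    side, value = max(deltas, key=lambda kv: abs(kv[1]))
    return DeltaResult(
        value,
        in_donor=side == "donor",
        in_acceptor=side == "acceptor",
        both_windows=len(deltas) == 2,
    )


def max_cryptic_site_score(
    context: ExonContext, donor_scorer, acceptor_scorer
) -> float:
    """Strongest candidate splice site created/overlapped by the variant.

    Scans every donor- and acceptor-shaped window containing the variant
    position on the mutant allele across the flank+exon+flank region,
    excluding windows whose implied junction coincides with an annotated
    junction of the target exon. Returns -inf only in the degenerate case
    of no scannable window (region shorter than both windows).
    """
    seq, off, exon_start, exon_end = context.mutant_region()
    junctions = set()
    if context.has_upstream:
        junctions.add(exon_start)  # first exonic base (acceptor junction)
    if context.has_downstream:
        junctions.add(exon_end)  # first intronic base (donor junction)
    best = -np.inf
    for scorer, exonic in (
        (donor_scorer, DONOR_EXONIC),
        (acceptor_scorer, ACCEPTOR_INTRONIC),
    ):
        length = scorer.window_length
        lo = max(0, off - length + 1)
        hi = min(off, len(seq) - length)
        for s in range(lo, hi + 1):
            if s + exonic in junctions:
                continue  # the natural site itself
            best = max(best, scorer.score(seq[s : s + length]))
    return best
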