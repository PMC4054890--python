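"""Shared helpers for the test suite (mock scorers, context builders)."""

from dataclasses import dataclass

from splicevar.genomic_context import Variant, resolve_context


def middle_exon_context(toy_locus, offset=7, alt=None):
    genome, models = toy_locus
    s2, _ = models.transcripts["txA"].exons[1]
    pos = s2 + offset
    ref = genome.base("chrT", pos)
    if alt is None:
        alt = "A" if ref != "A" else "G"
    return resolve_context(Variant("chrT", pos, ref, alt), models, genome)


@dataclass(frozen=True)
class CountScorer:
    """Mock splice-site scorer: counts a given base in the window."""

    base: str
    window_length: int
    kind: str = "mock"

    def score(self, window):
        if len(window) != self.window_length:
            raise ValueError("wrong window length")
        return float(window.count(self.base))


@dataclass(frozen=True)
class ConstScorer:
    value: float
    window_length: int
    kind: str = "mock"

    def score(self, window):
        return self.value
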