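"""Exonic splicing-regulatory (ESR) hexamer features.

A substitution is scanned with every 6-mer window that overlaps it (six
windows for interior positions, fewer near sequence ends). Each window's
wild-type and mutant hexamers are classified ESE / ESS / neutral against a
hexamer catalog, producing the nine-category ESR change profile. On top of
membership, the ESR hexamer score (ESR-HS) contrasts how often a given
hexamer — and the mutated position within it — is hit in a disease corpus
versus a neutral corpus:

    ESR-HS(t, k, j) = log2(S[t,k,disease] / S[t,k,neutral])
                    + log2(H[t,k,j,disease] / H[t,k,j,neutral])

where S are pseudocounted, normalized per-hexamer frequencies over the
transition type t in {ESEloss, ESEgain, ESSloss, ESSgain}, and H are
pseudocounted, normalized frequencies of the substituted position j in
0..5 within hexamer k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_context import VALID_BASES, ExonContext

log = logging.getLogger(__name__)

TRANSITION_NAMES = (
    "ese_loss",  # ESE -> neutral
    "ese_ese",  # ESE -> ESE
    "ese_gain",  # neutral -> ESE
    "ese_to_ess",  # ESE -> ESS (ESE loss and ESS gain)
    "neutral_neutral",
    "ess_ess",
    "ess_gain",  # neutral -> ESS
    "ess_loss",  # ESS -> neutral
    "ess_to_ese",  # ESS -> ESE (ESS loss and ESE gain)
)

_PAIR_TO_NAME = {
    ("ESE", "neutral"): "ese_loss",
    ("ESE", "ESE"): "ese_ese",
    ("neutral", "ESE"): "ese_gain",
    ("ESE", "ESS"): "ese_to_ess",
    ("neutral", "neutral"): "neutral_neutral",
    ("ESS", "ESS"): "ess_ess",
    ("neutral", "ESS"): "ess_gain",
    ("ESS", "neutral"): "ess_loss",
    ("ESS", "ESE"): "ess_to_ese",
}

EVENT_TYPES = ("ESEloss", "ESEgain", "ESSloss", "ESSgain")


class HexamerError(ValueError):
    pass


@dataclass(frozen=True)
class HexamerSet:
    ese: frozenset
    ess: frozenset
    provenance: str = ""

    def __post_init__(self):
        for motif in list(self.ese) + list(self.ess):
            if len(motif) != 6 or set(motif) - VALID_BASES:
                raise HexamerError(f"invalid hexamer {motif!r}")


def _read_motifs(path):
    motifs = []
    with open(path) as fh:
        for line in fh:
            m = line.strip().upper().replace("U", "T")
            if not m or m.startswith("#"):
                continue
            if len(m) != 6:
                raise HexamerError(f"{path}: motif {m!r} is not a hexamer")
            if set(m) - VALID_BASES:
                raise HexamerError(f"{path}: motif {m!r} has invalid characters")
            motifs.append(m)
    unique = set(motifs)
    if len(unique) < len(motifs):
        log.warning("%s: %d duplicate motifs collapsed", path, len(motifs) - len(unique))
    return unique


def load_hexamer_sets(ese_path, ess_path, collision: str = "error") -> HexamerSet:
    """Load ESE/ESS catalogs (one 6-mer per line, case-insensitive, U->T).

    ``collision`` controls motifs present in both files: 'error' (default),
    'prefer-ese', 'prefer-ess', or 'drop'.
    """
    ese = _read_motifs(ese_path)
    ess = _read_motifs(ess_path)
    both = ese & ess
    if both:
        if collision == "error":
            raise HexamerError(
                f"{len(both)} motifs present in both ESE and ESS lists"
            )
        if collision == "prefer-ese":
            ess -= both
        elif collision == "prefer-ess":
            ese -= both
        elif collision == "drop":
            ese -= both
            ess -= both
        else:
            raise ValueError(f"unknown collision policy {collision!r}")
    log.info("loaded %d ESE and %d ESS hexamers", len(ese), len(ess))
    return HexamerSet(frozenset(ese), frozenset(ess))


def classify_hexamer(hexamer: str, sets: HexamerSet) -> str:
    label, _ = classify_hexamer_full(hexamer, sets)
    return label


def classify_hexamer_full(hexamer: str, sets: HexamerSet):
    """(label, masked): hexamers containing N are neutral with masked=True."""
    if len(hexamer) != 6:
        raise HexamerError(f"not a hexamer: {hexamer!r}")
    if set(hexamer) - VALID_BASES:
        if set(hexamer) - (VALID_BASES | {"N"}):
            raise HexamerError(f"invalid alphabet in {hexamer!r}")
        return "neutral", True
    if hexamer in sets.ese:
        return "ESE", False
    if hexamer in sets.ess:
        return "ESS", False
    return "neutral", False


@dataclass
class EsrChangeProfile:
    counts: dict

    @property
    def n_windows(self) -> int:
        return sum(self.counts.values())

    def as_dict(self, prefix: str = "esr_") -> dict:
        return {prefix + k: v for k, v in self.counts.items()}


def _window_starts(length: int, offset: int):
    return range(max(0, offset - 5), min(offset, length - 6) + 1)


def esr_change_profile(
    sequence: str, variant_offset: int, alt_base: str, sets: HexamerSet,
    ref_base: str = None,
) -> EsrChangeProfile:
    """Nine-category transition counts over all hexamer windows covering
    the substitution. ``sequence`` is sense-strand pre-mRNA context and may
    span exon/intron boundaries."""
    if not (0 <= variant_offset < len(sequence)):
        raise IndexError("variant offset outside sequence")
    if ref_base is not None and sequence[variant_offset] != ref_base:
        raise ValueError(
            f"reference mismatch at offset {variant_offset}: "
            f"sequence has {sequence[variant_offset]}, expected {ref_base}"
        )
    counts = {name: 0 for name in TRANSITION_NAMES}
    for s in _window_starts(len(sequence), variant_offset):
        wt = sequence[s : s + 6]
        j = variant_offset - s
        mut = wt[:j] + alt_base + wt[j + 1 :]
        pair = (classify_hexamer(wt, sets), classify_hexamer(mut, sets))
        counts[_PAIR_TO_NAME[pair]] += 1
    return EsrChangeProfile(counts)


def wt_esr_overlap_counts(sequence: str, variant_offset: int, sets: HexamerSet):
    """How many wild-type ESE / ESS hexamers overlap the variant position."""
    in_ese = in_ess = 0
    for s in _window_starts(len(sequence), variant_offset):
        label = classify_hexamer(sequence[s : s + 6], sets)
        if label == "ESE":
            in_ese += 1
        elif label == "ESS":
            in_ess += 1
    return in_ese, in_ess


def esr_transition_events(
    sequence: str, variant_offset: int, alt_base: str, sets: HexamerSet
):
    """(type, hexamer k, position j) events realized by a substitution.

    For losses k is the wild-type hexamer, for gains the mutant hexamer;
    j is the substituted position within the window. ESE->ESS realizes
    both an ESEloss and an ESSgain (and symmetrically for ESS->ESE).
    """
    events = []
    for s in _window_starts(len(sequence), variant_offset):
        wt = sequence[s : s + 6]
        j = variant_offset - s
        mut = wt[:j] + alt_base + wt[j + 1 :]
        a = classify_hexamer(wt, sets)
        b = classify_hexamer(mut, sets)
        if a == "ESE" and b != "ESE":
            events.append(("ESEloss", wt, j))
        if a == "ESS" and b != "ESS":
            events.append(("ESSloss", wt, j))
        if b == "ESE" and a != "ESE":
            events.append(("ESEgain", mut, j))
        if b == "ESS" and a != "ESS":
            events.append(("ESSgain", mut, j))
    return events


@dataclass
class EsrHexamerTables:
    """Normalized, pseudocounted S and H tables behind ESR-HS.

    ``s_tables[t][corpus]`` maps hexamer -> probability (sums to 1 over the
    transition type's hexamer universe); ``h_tables[(t, k)][corpus]`` is a
    length-6 array over substituted positions (sums to 1).
    """

    universes: dict
    s_tables: dict
    h_tables: dict
    pseudocount: float
    corpus_sizes: dict = field(default_factory=dict)

    def score(self, t: str, hexamer: str, position: int) -> float:
        return esr_hs(self, t, hexamer, position)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in EVENT_TYPES:
            for k in self.universes[t]:
                for j in range(6):
                    rows.append(
                        {
                            "transition": t,
                            "hexamer": k,
                            "position": j,
                            "s_disease": self.s_tables[t]["disease"][k],
                            "s_neutral": self.s_tables[t]["neutral"][k],
                            "h_disease": self.h_tables[(t, k)]["disease"][j],
                            "h_neutral": self.h_tables[(t, k)]["neutral"][j],
                        }
                    )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_esr_hs_tables(
    disease_events, neutral_events, sets: HexamerSet, pseudocount: float = 1.0
) -> EsrHexamerTables:
    """Estimate S and H tables from (type, hexamer, position) event lists.

    The hexamer universe of ESEloss/ESEgain is the ESE catalog, of
    ESSloss/ESSgain the ESS catalog; every table cell receives the
    pseudocount, so all entries are strictly positive and each table
    normalizes to 1 regardless of how sparse the corpora are.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    universes = {
        "ESEloss": tuple(sorted(sets.ese)),
        "ESEgain": tuple(sorted(sets.ese)),
        "ESSloss": tuple(sorted(sets.ess)),
        "ESSgain": tuple(sorted(sets.ess)),
    }
    for t, u in universes.items():
        if not u:
            raise ValueError(f"empty hexamer universe for {t}")
    raw = {
        corpus: {t: {} for t in EVENT_TYPES}
        for corpus in ("disease", "neutral")
    }
    for corpus, events in (("disease", disease_events), ("neutral", neutral_events)):
        for t, k, j in events:
            if t not in universes:
                raise ValueError(f"unknown transition type {t!r}")
            if k not in set(universes[t]):
                raise ValueError(f"hexamer {k!r} not in universe of {t}")
            if not 0 <= j <= 5:
                raise ValueError(f"position {j} outside 0..5")
            raw[corpus][t].setdefault(k, np.zeros(6))[j] += 1

    s_tables = {}
    h_tables = {}
    for t in EVENT_TYPES:
        universe = universes[t]
        s_tables[t] = {}
        for corpus in ("disease", "neutral"):
            totals = {
                k: raw[corpus][t].get(k, np.zeros(6)).sum() for k in universe
            }
            denom = sum(totals.values()) + pseudocount * len(universe)
            s_tables[t][corpus] = {
                k: (totals[k] + pseudocount) / denom for k in universe
            }
        for k in universe:
            h_tables[(t, k)] = {}
            for corpus in ("disease", "neutral"):
                counts = raw[corpus][t].get(k, np.zeros(6))
                h_tables[(t, k)][corpus] = (counts + pseudocount) / (
                    counts.sum() + 6 * pseudocount
                )
    sizes = {
        "disease": sum(len(v) for v in raw["disease"].values()),
        "neutral": sum(len(v) for v in raw["neutral"].values()),
    }
    return EsrHexamerTables(universes, s_tables, h_tables, pseudocount, sizes)


def load_esr_hs_tables(path, sets: HexamerSet, pseudocount: float = 1.0):
    """Read tables back from the TSV written by EsrHexamerTables.save."""
    df = pd.read_csv(path, sep="\t")
    universes = {
        t: tuple(sorted(df.loc[df.transition == t, "hexamer"].unique()))
        for t in EVENT_TYPES
    }
    s_tables = {t: {"disease": {}, "neutral": {}} for t in EVENT_TYPES}
    h_tables = {}
    for (t, k), grp in df.groupby(["transition", "hexamer"]):
        grp = grp.sort_values("position")
        s_tables[t]["disease"][k] = float(grp.s_disease.iloc[0])
        s_tables[t]["neutral"][k] = float(grp.s_neutral.iloc[0])
        h_tables[(t, k)] = {
            "disease": grp.h_disease.to_numpy(),
            "neutral": grp.h_neutral.to_numpy(),
        }
    return EsrHexamerTables(universes, s_tables, h_tables, pseudocount)


def esr_hs(tables: EsrHexamerTables, t: str, hexamer: str, position: int) -> float:
    """The combined hexamer + position log2-ratio score; finite by the
    pseudocount construction."""
    if hexamer not in tables.s_tables[t]["disease"]:
        raise KeyError(f"hexamer {hexamer!r} unknown for transition {t}")
    if not 0 <= position <= 5:
        raise ValueError("position outside 0..5")
    s_d = tables.s_tables[t]["disease"][hexamer]
    s_n = tables.s_tables[t]["neutral"][hexamer]
    h_d = tables.h_tables[(t, hexamer)]["disease"][position]
    h_n = tables.h_tables[(t, hexamer)]["neutral"][position]
    return math.log2(s_d / s_n) + math.log2(h_d / h_n)


def variant_esr_hs_features(
    sequence: str,
    variant_offset: int,
    alt_base: str,
    sets: HexamerSet,
    tables: EsrHexamerTables,
    agg: str = "max",
) -> dict:
    """Per-variant ESR-HS features, one per transition type.

    Every overlapping window realizing a transition type contributes a
    score; the feature is the maximum (default) or sum over contributing
    windows, and 0 when no window realizes the type.
    """
    per_type = {t: [] for t in EVENT_TYPES}
    for t, k, j in esr_transition_events(sequence, variant_offset, alt_base, sets):
        per_type[t].append(esr_hs(tables, t, k, j))
    reduce = max if agg == "max" else sum
    if agg not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    return {
        f"esrhs_{t[:3].lower()}_{t[3:]}": (reduce(v) if v else 0.0)
        for t, v in per_type.items()
    }


@dataclass
class DensityProfile:
    ese_density_start: float
    ese_density_end: float
    ess_density_start: float
    ess_density_end: float
    intron_ess_density_up: float
    intron_ess_density_down: float
    undefined_regions: tuple = ()

    def as_dict(self) -> dict:
        return {
            "ese_density_start": self.ese_density_start,
            "ese_density_end": self.ese_density_end,
            "ess_density_start": self.ess_density_start,
            "ess_density_end": self.ess_density_end,
            "intron_ess_density_up": self.intron_ess_density_up,
            "intron_ess_density_down": self.intron_ess_density_down,
        }


def region_density(region: str, sets: HexamerSet, kind: str):
    """Fraction of hexamer windows in ``region`` classified in-set.

    Returns (density, defined). Regions shorter than one hexamer have no
    windows; the density is reported as 0 with defined=False.
    """
    n = len(region) - 5
    if n < 1:
        return 0.0, False
    hits = sum(
        classify_hexamer(region[s : s + 6], sets) == kind for s in range(n)
    )
    return hits / n, True


def esr_density(context: ExonContext, sets: HexamerSet) -> DensityProfile:
    """ESE/ESS densities over the target exon's first and last 50 bp (full
    exon when shorter than 100 bp) and ESS density over each 100 bp
    intronic flank (truncated flanks use the available sequence)."""
    exon = context.exon_seq
    if len(exon) < 100:
        start_region = end_region = exon
    else:
        start_region, end_region = exon[:50], exon[-50:]
    undefined = []

    def dens(region, kind, name):
        d, ok = region_density(region, sets, kind)
        if not ok:
            undefined.append(name)
        return d

    return DensityProfile(
        ese_density_start=dens(start_region, "ESE", "ese_start"),
        ese_density_end=dens(end_region, "ESE", "ese_end"),
        ess_density_start=dens(start_region, "ESS", "ess_start"),
        ess_density_end=dens(end_region, "ESS", "ess_end"),
        intron_ess_density_up=dens(context.upstream_intron_seq, "ESS", "intron_up"),
        intron_ess_density_down=dens(
            context.downstream_intron_seq, "ESS", "intron_down"
        ),
        undefined_regions=tuple(undefined),
    )
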