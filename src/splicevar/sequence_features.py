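"""Spectrum-kernel k-mer features, conservation lookups, and assembly of
the complete per-variant feature vector.

The k-mer spectrum is computed over an 11 bp window centred on the variant
(5 bp each side, genomic sense strand) for k = 3 and k = 4, separately for
the wild-type and mutant alleles, together with the mutant-minus-wild-type
differences. Conservation comes from two per-base tracks: a base-wise
score (phyloP-like, unbounded) and a conserved-element probability
(phastCons-like, in [0,1]).

A variant whose feature prerequisites cannot all be met (window truncated
at a contig end, missing conservation value, terminal exon without a
scored natural site) is excluded with a logged reason rather than padded —
feature vectors have no missing values by construction.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import esr_features as esr
from . import splice_sites as ss
from .genomic_context import (
    ExonContext,
    GeneModels,
    GenomeSequence,
    NotExonicError,
    Variant,
    VariantError,
    distance_to_nearest_splice_site,
    exon_gene_features,
    resolve_context,
)

log = logging.getLogger(__name__)

SPECTRUM_WINDOW = 11
KMERS3 = tuple("".join(p) for p in product("ACGT", repeat=3))
KMERS4 = tuple("".join(p) for p in product("ACGT", repeat=4))


class FeatureUnavailable(Exception):
    """A required feature cannot be computed; the variant is excluded."""


@dataclass
class Exclusion:
    variant_id: str
    reason: str


def _count_kmers(seq: str, k: int, index: dict) -> np.ndarray:
    out = np.zeros(len(index), dtype=float)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        try:
            out[index[kmer]] += 1
        except KeyError:
            raise ValueError(f"invalid k-mer {kmer!r}") from None
    return out


_IDX3 = {k: i for i, k in enumerate(KMERS3)}
_IDX4 = {k: i for i, k in enumerate(KMERS4)}


@dataclass
class KmerSpectrum:
    wt3: np.ndarray
    wt4: np.ndarray
    mut3: np.ndarray
    mut4: np.ndarray

    @property
    def diff3(self) -> np.ndarray:
        return self.mut3 - self.wt3

    @property
    def diff4(self) -> np.ndarray:
        return self.mut4 - self.wt4

    def as_dict(self) -> dict:
        out = {}
        for prefix, arr, kmers in (
            ("wt_k3_", self.wt3, KMERS3),
            ("wt_k4_", self.wt4, KMERS4),
            ("mut_k3_", self.mut3, KMERS3),
            ("mut_k4_", self.mut4, KMERS4),
            ("diff_k3_", self.diff3, KMERS3),
            ("diff_k4_", self.diff4, KMERS4),
        ):
            for kmer, v in zip(kmers, arr):
                out[prefix + kmer] = v
        return out


def spectrum_features(wt_window: str, mut_window: str) -> KmerSpectrum:
    """Dense 3-mer and 4-mer counts for both alleles of an 11 bp window."""
    for w in (wt_window, mut_window):
        if len(w) != SPECTRUM_WINDOW:
            raise ValueError(f"window must be {SPECTRUM_WINDOW} bp, got {len(w)}")
    return KmerSpectrum(
        wt3=_count_kmers(wt_window, 3, _IDX3),
        wt4=_count_kmers(wt_window, 4, _IDX4),
        mut3=_count_kmers(mut_window, 3, _IDX3),
        mut4=_count_kmers(mut_window, 4, _IDX4),
    )


@dataclass
class ConservationTrack:
    """Sparse per-base score map loaded from a bedGraph-like file."""

    kind: str  # 'basewise' or 'element'
    values: dict  # (contig, 0-based pos) -> float

    def lookup(self, contig: str, pos: int):
        return self.values.get((contig, pos))


def load_track(path, kind: str) -> ConservationTrack:
    """Read a 4-column bedGraph (contig, start, end, value; 0-based
    half-open) into a per-base map. Element-probability tracks must lie in
    [0,1]."""
    if kind not in ("basewise", "element"):
        raise ValueError(f"unknown track kind {kind!r}")
    df = pd.read_csv(
        path, sep="\t", names=["contig", "start", "end", "value"], comment="#"
    )
    values = {}
    for contig, start, end, value in df.itertuples(index=False):
        if kind == "element" and not 0.0 <= value <= 1.0:
            raise ValueError(
                f"element probability {value} outside [0,1] at {contig}:{start}"
            )
        for pos in range(int(start), int(end)):
            values[(contig, pos)] = float(value)
    return ConservationTrack(kind, values)


def conservation_scores(
    variant: Variant, basewise: ConservationTrack, element: ConservationTrack
):
    """Point lookups at the substitution site; missing positions exclude
    the variant (no imputation)."""
    b = basewise.lookup(variant.contig, variant.pos)
    e = element.lookup(variant.contig, variant.pos)
    if b is None or e is None:
        raise FeatureUnavailable(
            f"{variant.name}: conservation value missing at site"
        )
    return b, e


SCHEMA_VERSION = "1"


def feature_names() -> list:
    """The fixed, ordered feature schema (one row of the design matrix)."""
    names = ["dist_nearest_splice_site"]
    names += ["esr_" + t for t in esr.TRANSITION_NAMES]
    names += ["wt_overlap_ese", "wt_overlap_ess"]
    names += ["esrhs_ese_loss", "esrhs_ese_gain", "esrhs_ess_loss", "esrhs_ess_gain"]
    for prefix in ("wt_k3_", "mut_k3_", "diff_k3_"):
        names += [prefix + k for k in KMERS3]
    for prefix in ("wt_k4_", "mut_k4_", "diff_k4_"):
        names += [prefix + k for k in KMERS4]
    names += [
        "delta_natural_site",
        "max_cryptic_score",
        "conservation_basewise",
        "conservation_element",
        "natural_site_5p",
        "natural_site_3p",
        "upstream_intron_len",
        "downstream_intron_len",
        "ese_density_start",
        "ese_density_end",
        "ess_density_start",
        "ess_density_end",
        "intron_ess_density_up",
        "intron_ess_density_down",
        "internal_coding_exon",
        "exon_gc_pct",
        "exon_size",
        "constitutive_exon",
        "exon_number",
        "transcript_number",
    ]
    return names


FEATURE_NAMES = feature_names()


def schema_hash() -> str:
    payload = (SCHEMA_VERSION + "|" + "|".join(FEATURE_NAMES)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FeatureResources:
    """Everything needed to featurize a variant."""

    genome: GenomeSequence
    models: GeneModels
    hexamers: esr.HexamerSet
    esr_tables: esr.EsrHexamerTables
    donor_scorer: object
    acceptor_scorer: object
    basewise: ConservationTrack
    element: ConservationTrack
    flank: int = 100
    esr_hs_agg: str = "max"


def assemble_feature_vector(
    variant: Variant, context: ExonContext, res: FeatureResources
) -> dict:
    """Compute every schema field for one variant or raise
    FeatureUnavailable."""
    seq, off, _, _ = context.region()

    # 11 bp spectrum window on the sense strand; truncation excludes
    half = SPECTRUM_WINDOW // 2
    if off < half or off + half >= len(seq):
        raise FeatureUnavailable(f"{variant.name}: spectrum window truncated")
    wt_win = seq[off - half : off + half + 1]
    mut_win = wt_win[:half] + context.alt + wt_win[half + 1 :]
    spectrum = spectrum_features(wt_win, mut_win)

    profile = esr.esr_change_profile(seq, off, context.alt, res.hexamers, context.ref)
    in_ese, in_ess = esr.wt_esr_overlap_counts(seq, off, res.hexamers)
    hs = esr.variant_esr_hs_features(
        seq, off, context.alt, res.hexamers, res.esr_tables, agg=res.esr_hs_agg
    )
    densities = esr.esr_density(context, res.hexamers)

    strengths = ss.natural_site_strength(
        context, res.donor_scorer, res.acceptor_scorer
    )
    if strengths.five_prime is None or strengths.three_prime is None:
        raise FeatureUnavailable(
            f"{variant.name}: natural splice site score unavailable "
            f"({strengths.five_prime_absent or strengths.three_prime_absent})"
        )
    delta = ss.delta_natural_site(context, res.donor_scorer, res.acceptor_scorer)
    cryptic = ss.max_cryptic_site_score(
        context, res.donor_scorer, res.acceptor_scorer
    )
    if not np.isfinite(cryptic):
        raise FeatureUnavailable(f"{variant.name}: no scannable cryptic window")

    basewise, element = conservation_scores(variant, res.basewise, res.element)

    dist, _side = distance_to_nearest_splice_site(context)
    eg = exon_gene_features(context)

    row = {"dist_nearest_splice_site": float(dist)}
    row.update(profile.as_dict())
    row["wt_overlap_ese"] = in_ese
    row["wt_overlap_ess"] = in_ess
    row.update(hs)
    row.update(spectrum.as_dict())
    row["delta_natural_site"] = delta.value
    row["max_cryptic_score"] = cryptic
    row["conservation_basewise"] = basewise
    row["conservation_element"] = element
    row["natural_site_5p"] = strengths.five_prime
    row["natural_site_3p"] = strengths.three_prime
    row["upstream_intron_len"] = eg["upstream_intron_len"]
    row["downstream_intron_len"] = eg["downstream_intron_len"]
    row.update(densities.as_dict())
    row["internal_coding_exon"] = float(eg["internal_coding_exon"])
    row["exon_gc_pct"] = eg["exon_gc_pct"]
    row["exon_size"] = eg["exon_size"]
    row["constitutive_exon"] = float(eg["constitutive_exon"])
    row["exon_number"] = eg["exon_number"]
    row["transcript_number"] = eg["transcript_number"]

    missing = [k for k in FEATURE_NAMES if k not in row]
    extra = [k for k in row if k not in FEATURE_NAMES]
    if missing or extra:  # schema totality guard
        raise RuntimeError(f"schema mismatch: missing={missing} extra={extra}")
    return {k: float(row[k]) for k in FEATURE_NAMES}


def featurize_variants(variants, res: FeatureResources):
    """Featurize a collection of variants.

    Returns (DataFrame indexed by variant id with the full schema as
    columns, list of Exclusions). Variants that are not exonic, fail
    reference validation, or miss any feature are excluded and logged.
    """
    rows, index, excluded = [], [], []
    for v in variants:
        try:
            ctx = resolve_context(v, res.models, res.genome, flank=res.flank)
            rows.append(assemble_feature_vector(v, ctx, res))
            index.append(v.name)
        except (NotExonicError, VariantError, FeatureUnavailable) as exc:
            excluded.append(Exclusion(v.name, str(exc)))
            log.info("excluded %s: %s", v.name, exc)
    df = pd.DataFrame(rows, index=index, columns=FEATURE_NAMES)
    df.index.name = "variant_id"
    df.attrs["schema_hash"] = schema_hash()
    return df, excluded


def save_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="variant_id")


def load_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    if list(df.columns) != FEATURE_NAMES:
        raise ValueError("feature table does not match the current schema")
    df.attrs["schema_hash"] = schema_hash()
    return df
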