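"""VCF input/output (pysam-backed).

Reading splits multiallelic records into biallelic substitutions and skips
non-SNV alleles with a logged reason. Annotation writes three INFO keys:
SPV_SCORE (general score), SPV_CALL (SAV/SNV) and SPV_MECH
(mechanism:Z:P, comma-separated, confident hypotheses only).
"""

from __future__ import annotations

import logging

import pysam

from .genomic_context import VALID_BASES, Variant

log = logging.getLogger(__name__)


def read_vcf_variants(path):
    """Yield Variant objects for every biallelic SNV allele in a VCF."""
    skipped = 0
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if (
                    len(ref) != 1
                    or len(alt) != 1
                    or ref not in VALID_BASES
                    or alt not in VALID_BASES
                ):
                    skipped += 1
                    log.info(
                        "skipping non-SNV allele %s>%s at %s:%d",
                        ref,
                        alt,
                        rec.contig,
                        rec.pos,
                    )
                    continue
                vid = rec.id or f"{rec.contig}:{rec.pos}{ref}>{alt}"
                if rec.alts and len(rec.alts) > 1:
                    vid = f"{vid}_{alt}"
                out.append(Variant(rec.contig, rec.start, ref, alt, variant_id=vid))
    if skipped:
        log.info("skipped %d non-SNV alleles", skipped)
    return out


def write_annotated_vcf(in_path, out_path, annotations):
    """Copy a VCF adding SPV_* INFO fields.

    ``annotations`` maps variant id -> dict with keys 'score', 'call' and
    optionally 'mech' (list of (mechanism, z, p) tuples). Records without
    an annotation (e.g. excluded variants) pass through unchanged.
    """
    with pysam.VariantFile(str(in_path)) as vin:
        header = vin.header.copy()
        header.info.add("SPV_SCORE", 1, "Float", "Splicing-disruption general score")
        header.info.add("SPV_CALL", 1, "String", "SAV/SNV call at threshold 0.60")
        header.info.add(
            "SPV_MECH",
            ".",
            "String",
            "Confident mechanism hypotheses as mechanism:Z:P",
        )
        with pysam.VariantFile(str(out_path), "w", header=header) as vout:
            for rec in vin:
                ref = (rec.ref or "").upper()
                ann = None
                for alt in rec.alts or ():
                    vid = rec.id or f"{rec.contig}:{rec.pos}{ref}>{alt.upper()}"
                    if rec.alts and len(rec.alts) > 1:
                        vid = f"{vid}_{alt.upper()}"
                    ann = annotations.get(vid) or ann
                out_rec = rec.copy()
                out_rec.translate(header)  # adopt the SPV_* definitions
                if ann is not None:
                    out_rec.info["SPV_SCORE"] = float(ann["score"])
                    out_rec.info["SPV_CALL"] = ann["call"]
                    mech = ann.get("mech")
                    if mech:
                        out_rec.info["SPV_MECH"] = tuple(
                            f"{m.replace(' ', '_')}:{z:.3f}:{p:.3g}"
                            for m, z, p in mech
                        )
                vout.write(out_rec)
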