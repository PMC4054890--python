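"""Deterministic synthetic reference, annotation and variant sets.

The generator emulates, at desk scale, the data a splicing-impact
classifier is trained on: multi-exon genes with canonical GT..AG introns
and informative splice-site consensus, ESE/ESS hexamer catalogs, per-base
conservation tracks, and labeled variant sets in which splice-altering
variants (SAVs) are planted by mechanism:

  site_loss   weaken the exon's own donor (-1 G>T) or acceptor (+1 G>C);
  cryptic     a pre-planted near-donor 9-mer one substitution away from
              the consensus, activated by the variant;
  skipping    a planted ESE hexamer converted to a neutral hexamer
              (enhancer loss in a constitutive exon);
  retention   a planted ESS hexamer converted to neutral in a
              non-constitutive exon (one skipped by a second isoform).

Splice-neutral variants (SNVs) are rejection-sampled to avoid all planted
signals (site-strength delta capped, cryptic score capped); a small quota
sits at low-information natural-site window positions so neutral reference
distributions of the site delta have nonzero spread. Conserved-element
probabilities are drawn Beta(5,2) at true-SAV sites versus Beta(2,5)
background, and base-wise conservation N(1.5,1) versus N(0,1) — splice-
disrupting sites in real data sit in more conserved sequence, and the
fixtures reproduce that association. A configurable number of true SAVs is
mislabeled as negative (and duplicated into the unlabeled pool under a
fresh id) to exercise the self-training regimen. Everything derives from a
single seeded PCG64 stream; identical config gives byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .esr_features import HexamerSet
from .genomic_context import (
    GeneModels,
    GenomeSequence,
    TranscriptModel,
    Variant,
    reverse_complement,
    resolve_context,
)
from .splice_sites import (
    annotation_site_windows,
    delta_natural_site,
    max_cryptic_site_score,
    train_pwm_scorer,
)

BASES = "ACGT"
MECHANISM_CYCLE = ("site_loss", "cryptic", "skipping", "retention")
#: planted fixture mechanism -> hypothesis label used by the predictor
MECHANISM_LABELS = {
    "site_loss": "natural splice site loss",
    "cryptic": "cryptic splice site activation",
    "skipping": "exon skipping",
    "retention": "exon retention",
}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int
    n_genes: int = 100
    exons_per_gene: tuple = (4, 6)
    exon_len: tuple = (100, 160)
    intron_len: tuple = (150, 250)
    n_ese: int = 120
    n_ess: int = 80
    n_hot_ese: int = 10
    n_hot_ess: int = 8
    n_sav: int = 500
    n_snv: int = 600
    n_unlabeled: int = 200
    n_mislabeled: int = 5
    frac_minus: float = 0.3
    frac_two_isoform: float = 0.5
    snv_delta_cap: float = 0.75
    snv_cryptic_cap: float = 2.0
    snv_window_edge_frac: float = 0.05
    genes_per_contig: int = 40
    spacer_len: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_sav", "n_snv", "n_unlabeled", "n_mislabeled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rand_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _int_to_hexamer(i):
    out = []
    for _ in range(6):
        out.append(BASES[i % 4])
        i //= 4
    return "".join(out)


@dataclass
class _Gene:
    gene_id: str
    strand: str
    exon_seqs: list  # list[list[str]] mutable sense-strand exons
    intron_seqs: list
    skipped_exon: int  # sense index of the isoform-skipped exon, or -1
    contig: str = ""
    offset: int = 0  # genomic start of the gene's sense-built block

    @property
    def n_exons(self):
        return len(self.exon_seqs)

    def sense_exon_starts(self):
        starts, pos = [], 0
        for i, ex in enumerate(self.exon_seqs):
            starts.append(pos)
            pos += len(ex)
            if i < len(self.intron_seqs):
                pos += len(self.intron_seqs[i])
        return starts, pos

    def genomic_pos(self, exon_idx, off):
        starts, total = self.sense_exon_starts()
        p = starts[exon_idx] + off
        if self.strand == "-":
            p = total - 1 - p
        return self.offset + p


@dataclass
class World:
    config: FixtureConfig
    contigs: dict
    models: GeneModels
    hexamers: HexamerSet
    labeled: pd.DataFrame
    pool: pd.DataFrame
    phylop: dict
    phastcons: dict
    donor_windows: list
    acceptor_windows: list


_WORLD_CACHE = {}


def build_world(config: FixtureConfig) -> World:
    """Deterministically realize the whole synthetic study from the seed."""
    if config in _WORLD_CACHE:
        return _WORLD_CACHE[config]
    rng = np.random.default_rng(config.seed)

    # --- hexamer catalogs (disjoint by construction) ---
    # Hexamers fully determined by the planted site-loss/cryptic contexts
    # are kept out of the catalog: otherwise every such plant would carry
    # the same incidental ESR transition, systematically contaminating the
    # disease corpus with a non-ESR signal.
    context_hexamers = {
        "CAGCTA", "AGCTAA", "GCTAAG", "CTAAGT",  # dormant cryptic 9-mer
        "CAGGTA", "AGGTAA", "GGTAAG", "GTAAGT",  # activated / donor wt
        "ATGTAA", "TGTAAG",  # donor-loss mutant
    }
    order = rng.permutation(4096)
    hexes = []
    for c in order:
        h = _int_to_hexamer(int(c))
        if h not in context_hexamers:
            hexes.append(h)
        if len(hexes) == config.n_ese + config.n_ess:
            break
    ese = hexes[: config.n_ese]
    ess = hexes[config.n_ese :]
    hexamers = HexamerSet(frozenset(ese), frozenset(ess))
    in_catalog = set(ese) | set(ess)

    # "hot" hexamers carry the planted ESR signal; each has one fixed
    # (position, alt) recurrent substitution to a neutral hexamer, the way
    # recurrent disease mutations concentrate at particular motif positions
    def _hot_subs(pool):
        subs = {}
        for h in pool:
            options = [
                (p, b)
                for p in range(6)
                for b in BASES
                if b != h[p] and (h[:p] + b + h[p + 1 :]) not in in_catalog
            ]
            if options:
                subs[h] = options[int(rng.integers(len(options)))]
        return subs

    hot_ese_subs = _hot_subs(ese[: config.n_hot_ese])
    hot_ess_subs = _hot_subs(ess[: config.n_hot_ess])
    if not hot_ese_subs or not hot_ess_subs:
        raise RuntimeError("no mutable hot hexamers; enlarge catalogs")
    hot_ese = sorted(hot_ese_subs)
    hot_ess = sorted(hot_ess_subs)

    # --- genes, sense-strand ---
    genes = []
    lo_e, hi_e = config.exons_per_gene
    for g in range(config.n_genes):
        strand = "-" if rng.random() < config.frac_minus else "+"
        n_ex = int(rng.integers(max(3, lo_e), hi_e + 1))
        exons = []
        for _ in range(n_ex):
            L = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            ex = list(_rand_seq(rng, L))
            if rng.random() < 0.8:
                ex[0] = "G"
            if rng.random() < 0.85:
                ex[-2] = "A"
            if rng.random() < 0.9:
                ex[-1] = "G"
            exons.append(ex)
        introns = []
        for _ in range(n_ex - 1):
            L = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            mid = _rand_seq(rng, L - 6 - 14 - 3)
            pyr = "".join("CT"[i] for i in rng.integers(0, 2, size=14))
            introns.append("GTAAGT" + mid + pyr + "CAG")
        skipped = -1
        if rng.random() < config.frac_two_isoform and n_ex >= 4:
            skipped = int(rng.integers(1, n_ex - 1))
        genes.append(_Gene(f"gene{g:03d}", strand, exons, introns, skipped))

    # --- plan the splice-altering variants (sense coordinates) ---
    n_pool_sav = config.n_unlabeled // 2
    n_pool_snv = config.n_unlabeled - n_pool_sav
    n_sav_like = config.n_sav + config.n_mislabeled + n_pool_sav
    reserved = {}  # (gene_idx, exon_idx) -> list of (start, end) blocks
    used_ends = set()  # (gene_idx, exon_idx, side) for site-loss plants

    def overlaps(key, a, b):
        return any(a < e and s < b for s, e in reserved.get(key, []))

    def reserve(key, a, b):
        reserved.setdefault(key, []).append((a, b))

    retention_exons = [
        (gi, g.skipped_exon) for gi, g in enumerate(genes) if g.skipped_exon >= 0
    ]
    sav_plan = []  # (gene_idx, exon_idx, offset, ref, alt, mechanism)
    attempts = 0
    side_toggle = 0
    while len(sav_plan) < n_sav_like:
        attempts += 1
        if attempts > 100 * n_sav_like:
            raise RuntimeError("could not place planted variants; enlarge genome")
        i = len(sav_plan)
        if config.n_sav <= i < config.n_sav + config.n_mislabeled:
            # mislabeled negatives are *strong* planted positives with
            # pairwise-distinct signatures: unambiguous mechanisms, and the
            # site-loss ones alternate donor/acceptor sides (the global
            # side toggle), so no two are near-duplicates in feature space
            mech = ("cryptic", "site_loss")[i % 2]
        else:
            mech = MECHANISM_CYCLE[i % 4]
        if mech == "retention":
            if not retention_exons:
                raise RuntimeError("no non-constitutive exons for retention plants")
            gi, xi = retention_exons[int(rng.integers(len(retention_exons)))]
        else:
            gi = int(rng.integers(len(genes)))
            g = genes[gi]
            internal = [
                i for i in range(1, g.n_exons - 1) if i != g.skipped_exon
            ]
            if not internal:
                continue
            xi = internal[int(rng.integers(len(internal)))]
        g = genes[gi]
        ex = g.exon_seqs[xi]
        L = len(ex)
        key = (gi, xi)
        if mech == "site_loss":
            side = "donor" if side_toggle % 2 == 0 else "acceptor"
            if (gi, xi, side) in used_ends:
                continue
            if side == "donor":
                if overlaps(key, L - 9, L):
                    continue
                ex[-2], ex[-1] = "A", "G"
                off, ref, alt = L - 1, "G", "T"
                reserve(key, L - 9, L)
            else:
                if overlaps(key, 0, 9):
                    continue
                ex[0] = "G"
                off, ref, alt = 0, "G", "C"
                reserve(key, 0, 9)
            used_ends.add((gi, xi, side))
            side_toggle += 1
        elif mech == "cryptic":
            if L < 40:
                continue
            st = int(rng.integers(10, L - 19))
            if overlaps(key, st - 6, st + 15):
                continue
            ex[st : st + 9] = list("CAGCTAAGT")
            off, ref, alt = st + 3, "C", "G"
            reserve(key, st - 6, st + 15)
        else:  # skipping / retention: planted hexamer converted to neutral
            pool_h, subs = (
                (hot_ese, hot_ese_subs)
                if mech == "skipping"
                else (hot_ess, hot_ess_subs)
            )
            if L < 30:
                continue
            st = int(rng.integers(6, L - 12))
            if overlaps(key, st - 6, st + 12):
                continue
            h = pool_h[int(rng.integers(len(pool_h)))]
            p, b = subs[h]  # the hexamer's recurrent substitution
            ex[st : st + 6] = list(h)
            off, ref, alt = st + p, h[p], b
            reserve(key, st - 6, st + 12)
        sav_plan.append((gi, xi, off, ref, alt, mech))

    # --- assemble contigs and transcript models ---
    contigs = {}
    models = GeneModels()
    n_contigs = (config.n_genes + config.genes_per_contig - 1) // config.genes_per_contig
    parts = {f"chr{c + 1}": [] for c in range(n_contigs)}
    lengths = {name: 0 for name in parts}
    for gi, g in enumerate(genes):
        contig = f"chr{gi // config.genes_per_contig + 1}"
        block_parts = []
        ivals = []  # sense-local exon intervals
        pos = 0
        for i, ex in enumerate(g.exon_seqs):
            s = "".join(ex)
            ivals.append((pos, pos + len(s)))
            block_parts.append(s)
            pos += len(s)
            if i < len(g.intron_seqs):
                block_parts.append(g.intron_seqs[i])
                pos += len(g.intron_seqs[i])
        block = "".join(block_parts)
        spacer = _rand_seq(rng, config.spacer_len)
        g.contig = contig
        g.offset = lengths[contig]
        total = len(block)
        if g.strand == "-":
            block = reverse_complement(block)
            ivals = [(total - e, total - s) for s, e in ivals]
            ivals.reverse()  # back to ascending genomic order
        exon_ivals = tuple(
            (g.offset + s, g.offset + e) for s, e in sorted(ivals)
        )
        parts[contig].extend([block, spacer])
        lengths[contig] += total + config.spacer_len

        cds = (exon_ivals[0][0], exon_ivals[-1][1])
        models.add(
            TranscriptModel(
                transcript_id=f"{g.gene_id}.tA",
                gene_id=g.gene_id,
                contig=contig,
                strand=g.strand,
                exons=exon_ivals,
                cds_start=cds[0],
                cds_end=cds[1],
            )
        )
        if g.skipped_exon >= 0:
            skip_gi = (
                g.skipped_exon
                if g.strand == "+"
                else g.n_exons - 1 - g.skipped_exon
            )
            short = tuple(
                iv for i, iv in enumerate(exon_ivals) if i != skip_gi
            )
            models.add(
                TranscriptModel(
                    transcript_id=f"{g.gene_id}.tB",
                    gene_id=g.gene_id,
                    contig=contig,
                    strand=g.strand,
                    exons=short,
                    cds_start=cds[0],
                    cds_end=cds[1],
                )
            )
    contigs = {name: "".join(chunks) for name, chunks in parts.items()}
    genome = GenomeSequence(contigs)
    donors, acceptors = annotation_site_windows(genome, models)
    donor_scorer = train_pwm_scorer(donors, "donor")
    acceptor_scorer = train_pwm_scorer(acceptors, "acceptor")

    # --- materialize planted SAVs as genomic-coordinate variants ---
    rows = []
    taken = {}  # contig -> set of blocked positions

    def block(contig, pos, pad=6):
        taken.setdefault(contig, set()).update(range(pos - pad, pos + pad + 1))

    def is_blocked(contig, pos):
        return pos in taken.get(contig, set())

    for vi, (gi, xi, off, ref, alt, mech) in enumerate(sav_plan):
        g = genes[gi]
        pos = g.genomic_pos(xi, off)
        if g.strand == "-":
            ref_g, alt_g = reverse_complement(ref), reverse_complement(alt)
        else:
            ref_g, alt_g = ref, alt
        assert genome.base(g.contig, pos) == ref_g
        rows.append(
            {
                "contig": g.contig,
                "pos0": pos,
                "ref": ref_g,
                "alt": alt_g,
                "hidden_label": "SAV",
                "mechanism": mech,
            }
        )
        block(g.contig, pos)

    # --- rejection-sampled neutral variants ---
    n_snv_like = config.n_snv - config.n_mislabeled + n_pool_snv
    n_edge = int(round(config.snv_window_edge_frac * n_snv_like))
    snv_rows = []
    attempts = 0
    while len(snv_rows) < n_snv_like:
        attempts += 1
        if attempts > 400 * max(1, n_snv_like):
            raise RuntimeError("could not place neutral variants")
        gi = int(rng.integers(len(genes)))
        g = genes[gi]
        internal = list(range(1, g.n_exons - 1))
        xi = internal[int(rng.integers(len(internal)))]
        L = len(g.exon_seqs[xi])
        if len(snv_rows) < n_edge:
            off = L - 3  # low-information donor-window position
        else:
            off = int(rng.integers(0, L))
        if overlaps((gi, xi), off, off + 1):
            continue
        pos = g.genomic_pos(xi, off)
        if is_blocked(g.contig, pos):
            continue
        ref = g.exon_seqs[xi][off]
        alt = BASES[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        if g.strand == "-":
            ref_g, alt_g = reverse_complement(ref), reverse_complement(alt)
        else:
            ref_g, alt_g = ref, alt
        try:
            v = Variant(g.contig, pos, ref_g, alt_g, variant_id="probe")
            ctx = resolve_context(v, models, genome)
        except Exception:
            continue
        if abs(delta_natural_site(ctx, donor_scorer, acceptor_scorer).value) > (
            config.snv_delta_cap
        ):
            continue
        if (
            max_cryptic_site_score(ctx, donor_scorer, acceptor_scorer)
            > config.snv_cryptic_cap
        ):
            continue
        snv_rows.append(
            {
                "contig": g.contig,
                "pos0": pos,
                "ref": ref_g,
                "alt": alt_g,
                "hidden_label": "SNV",
                "mechanism": ".",
            }
        )
        block(g.contig, pos)

    # --- split plan into labeled / mislabeled / pool ---
    sav_rows = rows
    labeled_rows = []
    pool_rows = []
    vid = 0

    def new_id():
        nonlocal vid
        vid += 1
        return f"v{vid:06d}"

    # mislabeled SAVs spread across mechanisms (round-robin order of plan)
    for i, r in enumerate(sav_rows[: config.n_sav]):
        labeled_rows.append({**r, "id": new_id(), "label": "SAV"})
    mislabeled = []
    for r in sav_rows[config.n_sav : config.n_sav + config.n_mislabeled]:
        row = {**r, "id": new_id(), "label": "SNV", "mislabeled": True}
        labeled_rows.append(row)
        mislabeled.append(row)
    for r in sav_rows[config.n_sav + config.n_mislabeled :]:
        pool_rows.append({**r, "id": new_id()})
    for r in snv_rows[: config.n_snv - config.n_mislabeled]:
        labeled_rows.append({**r, "id": new_id(), "label": "SNV"})
    for r in snv_rows[config.n_snv - config.n_mislabeled :]:
        pool_rows.append({**r, "id": new_id()})
    # duplicates of the mislabeled examples, fresh ids, for self-training
    for row in mislabeled:
        pool_rows.append({**row, "id": row["id"] + "_u", "original_id": row["id"]})

    labeled = pd.DataFrame(labeled_rows)
    if "mislabeled" not in labeled.columns:
        labeled["mislabeled"] = False
    labeled["mislabeled"] = labeled["mislabeled"].notna() & labeled[
        "mislabeled"
    ].astype(bool)
    pool = pd.DataFrame(pool_rows)
    if "original_id" not in pool.columns:
        pool["original_id"] = ""
    pool["original_id"] = pool["original_id"].fillna("")

    # --- conservation tracks over every exonic base ---
    exonic = set()
    for tx in models.transcripts.values():
        for s, e in tx.exons:
            exonic.update((tx.contig, p) for p in range(s, e))
    phylop, phastcons = {}, {}
    for key in sorted(exonic):
        phylop[key] = float(rng.normal(0.0, 1.0))
        phastcons[key] = float(rng.beta(2, 5))
    sav_sites = {
        (r["contig"], r["pos0"])
        for r in labeled_rows + pool_rows
        if r["hidden_label"] == "SAV"
    }
    for key in sorted(sav_sites):
        phylop[key] = float(rng.normal(1.5, 1.0))
        phastcons[key] = float(rng.beta(5, 2))

    world = World(
        config=config,
        contigs=contigs,
        models=models,
        hexamers=hexamers,
        labeled=labeled,
        pool=pool,
        phylop=phylop,
        phastcons=phastcons,
        donor_windows=donors,
        acceptor_windows=acceptors,
    )
    _WORLD_CACHE[config] = world
    return world


# ---------------------------------------------------------------- writers


def _write_fasta(path, contigs):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_gtf(path, models: GeneModels):
    with open(path, "w") as fh:
        for tid in sorted(models.transcripts):
            tx = models.transcripts[tid]
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.contig}\tsynthetic\texon\t{s + 1}\t{e}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
                lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
                if lo < hi:
                    fh.write(
                        f"{tx.contig}\tsynthetic\tCDS\t{lo + 1}\t{hi}\t.\t"
                        f"{tx.strand}\t0\t{attrs}\n"
                    )


def _write_bedgraph(path, values):
    """Per-base map -> bedGraph, merging runs of equal adjacent values."""
    with open(path, "w") as fh:
        run = None  # (contig, start, end, value)
        for (contig, pos), v in sorted(values.items()):
            if run and run[0] == contig and run[2] == pos and run[3] == v:
                run = (contig, run[1], pos + 1, v)
            else:
                if run:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")
                run = (contig, pos, pos + 1, v)
        if run:
            fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")


def _write_lines(path, lines):
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def _variant_frame(df: pd.DataFrame, columns) -> pd.DataFrame:
    out = df.copy()
    out["pos"] = out["pos0"] + 1  # 1-based in files
    return out[columns]


def _write_vcf(path, df: pd.DataFrame, contigs):
    header = pysam.VariantHeader()
    for name, seq in contigs.items():
        header.contigs.add(name, length=len(seq))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, r in df.sort_values(["contig", "pos0"]).iterrows():
            rec = vcf.new_record(
                contig=r["contig"],
                start=int(r["pos0"]),
                stop=int(r["pos0"]) + 1,
                alleles=(r["ref"], r["alt"]),
                id=r["id"],
            )
            vcf.write(rec)


# ------------------------------------------------------------- public API


def generate_reference(config: FixtureConfig, outdir) -> dict:
    """Write the reference bundle; returns a dict of file paths.

    Files: genome FASTA, GTF annotation, ESE/ESS hexamer lists, base-wise
    and element-probability conservation bedGraphs, and donor/acceptor
    training windows for the splice-site scorer.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = build_world(config)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "ese": outdir / "ese.txt",
        "ess": outdir / "ess.txt",
        "phylop": outdir / "basewise.bedgraph",
        "phastcons": outdir / "element.bedgraph",
        "donor_sites": outdir / "donor_sites.txt",
        "acceptor_sites": outdir / "acceptor_sites.txt",
    }
    _write_fasta(paths["fasta"], world.contigs)
    _write_gtf(paths["gtf"], world.models)
    _write_lines(paths["ese"], sorted(world.hexamers.ese))
    _write_lines(paths["ess"], sorted(world.hexamers.ess))
    _write_bedgraph(paths["phylop"], world.phylop)
    _write_bedgraph(paths["phastcons"], world.phastcons)
    _write_lines(paths["donor_sites"], world.donor_windows)
    _write_lines(paths["acceptor_sites"], world.acceptor_windows)
    with open(outdir / "config.json", "w") as fh:
        json.dump({"seed": config.seed}, fh)
    return {k: str(v) for k, v in paths.items()}


def generate_variants(config: FixtureConfig, outdir) -> dict:
    """Write the labeled variant set (TSV + VCF).

    The TSV keeps the presented ``label`` column used for training plus
    synthetic ground truth (``hidden_label``, ``mechanism``, ``mislabeled``)
    used only for scoring recovery.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = build_world(config)
    cols = [
        "id",
        "contig",
        "pos",
        "ref",
        "alt",
        "label",
        "hidden_label",
        "mechanism",
        "mislabeled",
    ]
    df = _variant_frame(world.labeled, cols)
    tsv = outdir / "labeled.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    vcf = outdir / "labeled.vcf"
    _write_vcf(vcf, world.labeled, world.contigs)
    return {"tsv": str(tsv), "vcf": str(vcf)}


def generate_unlabeled_pool(config: FixtureConfig, outdir) -> dict:
    """Write the unlabeled pool plus the hidden-label sidecar key file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = build_world(config)
    pool_tsv = outdir / "unlabeled.tsv"
    _variant_frame(world.pool, ["id", "contig", "pos", "ref", "alt"]).to_csv(
        pool_tsv, sep="\t", index=False
    )
    key_tsv = outdir / "unlabeled_key.tsv"
    _variant_frame(
        world.pool, ["id", "hidden_label", "mechanism", "original_id"]
    ).to_csv(key_tsv, sep="\t", index=False)
    vcf = outdir / "unlabeled.vcf"
    _write_vcf(vcf, world.pool, world.contigs)
    return {"tsv": str(pool_tsv), "key": str(key_tsv), "vcf": str(vcf)}


def variants_from_frame(df: pd.DataFrame, pos_col: str = "pos"):
    """Variant objects from a loaded fixture table (1-based positions)."""
    return [
        Variant(
            contig=str(r["contig"]),
            pos=int(r[pos_col]) - 1,
            ref=r["ref"],
            alt=r["alt"],
            variant_id=str(r["id"]),
            label=r.get("label"),
        )
        for r in df.to_dict("records")
    ]
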