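"""Synthetic ATAC-seq / RNA-seq study generator with known ground truth.

Emulates a two-group (cattle-yak-like "CY" vs yak-like "Y") by three-replicate
testis chromatin-accessibility study at desk scale: a small uniform-ACGT
genome with non-overlapping gene models, an open-chromatin peak landscape
preferentially placed at promoters, Tn5 fragments with the characteristic
bimodal (nucleosome-free + mono-nucleosome) insert-length mixture, a planted
set of group-differential peaks with known log2 fold changes, motif
occurrences planted inside opened differential peaks, and gene expression
positively coupled to promoter openness with a planted DEG set.

Every quantity a downstream stage is supposed to recover (differential peak
ids and effect sizes, motif positions, DE genes) is recorded in
:class:`GroundTruth`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeAnnotation, IntervalSet, nearest_tss

__all__ = [
    "ConfigError",
    "SynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_genome",
    "simulate_peak_landscape",
    "simulate_fragments",
    "simulate_expression",
    "plant_motifs",
    "simulate_study",
    "write_study",
    "default_pfms",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# stage tags entering the seed stream so stages draw independent substreams
_STAGE_GENOME, _STAGE_PEAKS, _STAGE_FRAGS, _STAGE_EXPR, _STAGE_MOTIF = range(5)


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


def _label_code(label: str) -> int:
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def _rng(cfg_seed: int, *context: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), *context]))


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults describe the study conditions the pipeline is exercised under:
    two groups x 3 replicates, a 2 x 2 Mb genome with 250 genes, 480 peaks of
    which half sit within 1 kb of a TSS, 120 differential peaks at
    |log2FC| = 1, NB dispersion 0.1, 100k fragments/sample with a
    nucleosome-free (75 +/- 20 bp) / mono-nucleosome (200 +/- 30 bp) insert
    mixture, and unit openness-expression coupling.
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 250
    n_peaks_per_group: int = 480
    frac_promoter_peaks: float = 0.5
    n_differential: int = 120
    planted_lfc: float = 1.0
    diff_up_frac: float = 0.5
    dispersion: float = 0.1
    depth_per_sample: int = 100_000
    background_rate: float = 0.2
    frag_len_nfr_mean: float = 75.0
    frag_len_nfr_sd: float = 20.0
    frag_len_mono_mean: float = 200.0
    frag_len_mono_sd: float = 30.0
    nfr_weight: float = 0.65
    peak_width_mean: float = 500.0
    peak_width_sd: float = 100.0
    motif_id: str = "SYN0001.1"
    motif_plant_rate: float = 0.6
    expr_coupling: float = 1.0
    n_de_genes: int = 60
    de_couple_frac: float = 0.7
    n_replicates: int = 3
    groups: tuple = ("CY", "Y")
    elevated_group: str = "CY"
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_promoter_peaks", "background_rate", "nfr_weight",
                     "motif_plant_rate", "diff_up_frac", "de_couple_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.n_differential > self.n_peaks_per_group:
            raise ConfigError("n_differential exceeds n_peaks_per_group")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.depth_per_sample <= 0:
            raise ConfigError("depth_per_sample must be positive")
        if self.chrom_length <= 10 * 3000:
            raise ConfigError("chrom_length too small for 3 kb flank analyses")
        if self.elevated_group not in self.groups:
            raise ConfigError("elevated_group must be one of groups")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Everything the downstream stages are supposed to recover.

    ``peaks`` columns: peak_id, chrom, start, end, weight (relative
    accessibility), lfc (signed planted log2FC, 0 for non-differential),
    promoter_gene (gene id when the peak was placed at a promoter, else "").
    """

    peaks: pd.DataFrame
    motif_occurrences: list = field(default_factory=list)
    de_genes: dict = field(default_factory=dict)

    @property
    def differential_ids(self) -> set:
        return set(self.peaks.loc[self.peaks["lfc"] != 0, "peak_id"])

    @property
    def opened_ids(self) -> set:
        """Peaks planted with increased accessibility in the elevated group."""
        return set(self.peaks.loc[self.peaks["lfc"] > 0, "peak_id"])

    def true_peaks(self, group: str | None = None) -> IntervalSet:
        """The planted peak intervals (identical landscape for both groups)."""
        df = self.peaks[["chrom", "start", "end", "peak_id"]].rename(
            columns={"peak_id": "name"}
        )
        return IntervalSet(df)

    def to_json(self, path) -> None:
        payload = {
            "peaks": self.peaks.to_dict(orient="list"),
            "motif_occurrences": self.motif_occurrences,
            "de_genes": self.de_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            peaks=pd.DataFrame(payload["peaks"]),
            motif_occurrences=[tuple(o) for o in payload["motif_occurrences"]],
            de_genes=payload["de_genes"],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_MIN_GENE_LEN, _MAX_GENE_LEN = 1500, 4000
_MIN_GAP = 200
_MIN_SEGMENT = 50  # smallest exon or intron


def simulate_genome(cfg: SynthConfig):
    """Simulate the genome: gene models plus i.i.d. uniform-ACGT sequence.

    Genes are non-overlapping, strand-random, each with 2-4 exons and 5'/3'
    UTRs carved from the terminal exons.  Returns ``(annotation, sequences)``
    where sequences maps chrom -> string.  Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_GENOME)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: int(cfg.chrom_length) for c in chrom_names}

    per_chrom = [
        cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
        for i in range(cfg.n_chroms)
    ]
    genes, exons, utr5, utr3 = [], [], [], []
    gid_counter = 0
    for chrom, n_c in zip(chrom_names, per_chrom):
        if n_c == 0:
            continue
        lengths = rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1, size=n_c)
        needed = int(lengths.sum()) + (n_c + 1) * _MIN_GAP
        if needed > cfg.chrom_length:
            raise ConfigError(
                f"{n_c} genes (total {lengths.sum()} bp + gaps) do not fit on "
                f"{chrom} of length {cfg.chrom_length}"
            )
        slack = cfg.chrom_length - needed
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for k in range(n_c):
            pos += _MIN_GAP + int(extra[k])
            start, end = pos, pos + int(lengths[k])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{gid_counter:05d}"
            gid_counter += 1
            tss = start if strand == "+" else end - 1
            genes.append((gid, chrom, strand, start, end, tss))
            # 2-4 exons: 2k-1 alternating exon/intron segments
            k_ex = int(rng.integers(2, 5))
            n_seg = 2 * k_ex - 1
            w = rng.dirichlet(np.full(n_seg, 2.0))
            seg = _MIN_SEGMENT + np.floor(w * (lengths[k] - _MIN_SEGMENT * n_seg)).astype(int)
            seg[-1] += int(lengths[k]) - int(seg.sum())
            bounds = start + np.concatenate([[0], np.cumsum(seg)])
            ex_iv = [(int(bounds[j]), int(bounds[j + 1])) for j in range(0, n_seg, 2)]
            for s, e in ex_iv:
                exons.append((gid, chrom, s, e))
            # UTRs carved from the strand-aware first / last exon
            first, last = (ex_iv[0], ex_iv[-1]) if strand == "+" else (ex_iv[-1], ex_iv[0])
            u5 = min(100, (first[1] - first[0]) // 2)
            u3 = min(150, (last[1] - last[0]) // 2)
            if strand == "+":
                utr5.append((gid, chrom, first[0], first[0] + u5))
                utr3.append((gid, chrom, last[1] - u3, last[1]))
            else:
                utr5.append((gid, chrom, first[1] - u5, first[1]))
                utr3.append((gid, chrom, last[0], last[0] + u3))

    sub_cols = ["gene_id", "chrom", "start", "end"]
    annotation = GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "start", "end", "tss"]),
        exons=pd.DataFrame(exons, columns=sub_cols),
        five_prime_utr=pd.DataFrame(utr5, columns=sub_cols),
        three_prime_utr=pd.DataFrame(utr3, columns=sub_cols),
        chrom_sizes=chrom_sizes,
    )
    sequences = {
        c: _BASES[rng.integers(0, 4, size=chrom_sizes[c])].tobytes().decode()
        for c in chrom_names
    }
    return annotation, sequences


# ---------------------------------------------------------------------------
# peak landscape
# ---------------------------------------------------------------------------


def simulate_peak_landscape(annotation: GenomeAnnotation, cfg: SynthConfig) -> GroundTruth:
    """Plant the open-chromatin landscape with known differential peaks.

    ``frac_promoter_peaks`` of the peaks are centred within 1 kb of a TSS
    (one gene each, sampled without replacement); the remainder are uniform.
    ``n_differential`` peaks receive a signed planted log2FC: a
    ``diff_up_frac`` fraction (rounded down) gets +planted_lfc (more open in
    the elevated group), the rest -planted_lfc.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_PEAKS)
    n = cfg.n_peaks_per_group
    n_prom = int(round(cfg.frac_promoter_peaks * n))
    if n_prom > annotation.n_genes():
        raise ConfigError(
            f"{n_prom} promoter peaks requested but only {annotation.n_genes()} genes"
        )
    sizes = annotation.chrom_sizes
    chrom_names = sorted(sizes)
    widths = np.maximum(
        np.round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, size=n)), 200
    ).astype(np.int64)

    rows = []
    gene_pick = rng.choice(annotation.n_genes(), size=n_prom, replace=False)
    gdf = annotation.genes
    for j in range(n_prom):
        g = gdf.iloc[int(gene_pick[j])]
        # TSS-concentrated placement: accessibility is highest at the TSS
        offset = int(np.clip(np.round(rng.normal(0.0, 300.0)), -800, 800))
        center = int(g["tss"]) + offset
        w = int(widths[j])
        start = max(0, min(center - w // 2, sizes[g["chrom"]] - w))
        rows.append((g["chrom"], start, start + w, g["gene_id"]))
    size_arr = np.array([sizes[c] for c in chrom_names], dtype=float)
    for j in range(n_prom, n):
        w = int(widths[j])
        ci = int(rng.choice(len(chrom_names), p=size_arr / size_arr.sum()))
        chrom = chrom_names[ci]
        start = int(rng.integers(0, sizes[chrom] - w + 1))
        rows.append((chrom, start, start + w, ""))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "promoter_gene"])
    peaks["weight"] = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"peak_{i:05d}" for i in range(n)])

    lfc = np.zeros(n)
    if cfg.n_differential > 0:
        pick = rng.choice(n, size=cfg.n_differential, replace=False)
        n_up = int(np.floor(cfg.n_differential * cfg.diff_up_frac))
        lfc[pick[:n_up]] = cfg.planted_lfc
        lfc[pick[n_up:]] = -cfg.planted_lfc
    peaks["lfc"] = lfc
    return GroundTruth(peaks=peaks)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


def simulate_fragments(
    truth: GroundTruth, group: str, replicate: int, cfg: SynthConfig
) -> IntervalSet:
    """Simulate one sample's Tn5 fragments as genomic intervals.

    Per-peak fragment counts are NB with mean
    ``(1 - background_rate) * depth * weight_norm * 2^lfc`` (the fold change
    applied only in the elevated group) and dispersion alpha
    (variance mu + alpha mu^2).  Fragment midpoints are Normal(peak centre,
    width/4); insert lengths come from the nucleosome-free /
    mono-nucleosome two-Gaussian mixture floored at 20 bp.  A
    ``background_rate`` fraction of fragments is uniform over the genome.
    Deterministic per (seed, group, replicate).
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_FRAGS, _label_code(group), int(replicate))
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: int(cfg.chrom_length) for c in chrom_names}

    pk = truth.peaks
    n_bg = int(round(cfg.depth_per_sample * cfg.background_rate))
    n_fg = cfg.depth_per_sample - n_bg

    w = pk["weight"].to_numpy()
    mult = np.power(2.0, pk["lfc"].to_numpy()) if group == cfg.elevated_group else 1.0
    mu = n_fg * (w / w.sum()) * mult
    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    centers = ((pk["start"] + pk["end"]) // 2).to_numpy()
    widths = (pk["end"] - pk["start"]).to_numpy()
    mids = rng.normal(np.repeat(centers, counts), np.repeat(widths, counts) / 4.0)
    frag_chrom = np.repeat(pk["chrom"].to_numpy(), counts)

    # background, uniform over the genome
    size_arr = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    bg_ci = rng.choice(len(chrom_names), size=n_bg, p=size_arr / size_arr.sum())
    bg_mid = rng.random(n_bg) * size_arr[bg_ci]
    mids = np.concatenate([mids, bg_mid])
    frag_chrom = np.concatenate([frag_chrom, np.array(chrom_names, dtype=object)[bg_ci]])

    m = len(mids)
    is_nfr = rng.random(m) < cfg.nfr_weight
    lens = np.where(
        is_nfr,
        rng.normal(cfg.frag_len_nfr_mean, cfg.frag_len_nfr_sd, size=m),
        rng.normal(cfg.frag_len_mono_mean, cfg.frag_len_mono_sd, size=m),
    )
    lens = np.maximum(np.round(lens), 20).astype(np.int64)

    csize = np.array([chrom_sizes[c] for c in frag_chrom], dtype=np.int64)
    mids = np.clip(np.round(mids), 0, csize - 1).astype(np.int64)
    lens = np.minimum(lens, csize)
    starts = np.clip(mids - lens // 2, 0, csize - lens)
    df = pd.DataFrame(
        {"chrom": frag_chrom, "start": starts, "end": starts + lens}
    )
    return IntervalSet(df, chrom_sizes)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    annotation: GenomeAnnotation, truth: GroundTruth, cfg: SynthConfig
):
    """Simulate gene counts coupled to promoter openness.

    Per-gene log2 mean expression = baseline + expr_coupling * z(openness),
    where openness is the summed weight of peaks centred within 1 kb of the
    gene's TSS and z() standardizes across genes.  ``n_de_genes`` genes get
    an extra +/-1 log2 shift in the elevated group (recorded in
    ``truth.de_genes``).  Counts are NB with the configured dispersion and
    scale with exon length, so FPKM recovers the planted expression level.

    Returns ``(counts, lengths)``: counts indexed by gene_id with columns
    ``<group>_<rep>``; lengths a gene_id -> summed exon bp Series.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_EXPR)
    genes = annotation.genes
    n = len(genes)

    centers = truth.true_peaks()
    near = nearest_tss(centers, annotation)
    wsum = pd.Series(0.0, index=genes["gene_id"])
    close = near["abs_distance"] <= 1000
    contrib = pd.DataFrame(
        {"gene_id": near.loc[close, "gene_id"],
         "w": truth.peaks.loc[close.to_numpy().nonzero()[0], "weight"].to_numpy()}
    )
    if len(contrib):
        add = contrib.groupby("gene_id")["w"].sum()
        wsum.loc[add.index] = add.to_numpy()
    openness = wsum.to_numpy()
    z = (openness - openness.mean()) / (openness.std() if openness.std() > 0 else 1.0)

    baseline = rng.normal(np.log2(100.0), 1.0, size=n)
    log2_mu = baseline + cfg.expr_coupling * z

    de_shift = np.zeros(n)
    if cfg.n_de_genes > 0:
        n_de = min(cfg.n_de_genes, n)
        gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
        # a de_couple_frac share of DE genes is drawn from genes whose
        # promoter peak is itself differential, sign-matched, so accessibility
        # and expression change together for most DE genes
        diff_prom = truth.peaks[(truth.peaks["lfc"] != 0) & (truth.peaks["promoter_gene"] != "")]
        cand = diff_prom.drop_duplicates("promoter_gene")
        n_couple = min(int(round(cfg.de_couple_frac * n_de)), len(cand))
        picked: dict = {}
        if n_couple > 0:
            rows = rng.choice(len(cand), size=n_couple, replace=False)
            for ri in sorted(int(r) for r in rows):
                r = cand.iloc[ri]
                picked[gene_pos[r["promoter_gene"]]] = float(np.sign(r["lfc"]))
        free = np.array([i for i in range(n) if i not in picked])
        n_rest = n_de - len(picked)
        rest = rng.choice(free, size=n_rest, replace=False)
        half = n_rest // 2
        for j, i in enumerate(int(x) for x in rest):
            picked[i] = 1.0 if j < half else -1.0
        for i, s in picked.items():
            de_shift[i] = s
        truth.de_genes = {
            genes["gene_id"].iloc[i]: float(s) for i, s in sorted(picked.items())
        }

    exon_len = annotation.exons.assign(w=lambda d: d["end"] - d["start"]).groupby(
        "gene_id"
    )["w"].sum()
    lengths = exon_len.reindex(genes["gene_id"]).fillna(
        genes.set_index("gene_id")["end"] - genes.set_index("gene_id")["start"]
    ).astype(int)

    cols = {}
    lenfac = lengths.to_numpy() / 1000.0
    for group in cfg.groups:
        shift = de_shift if group == cfg.elevated_group else 0.0
        mu = np.power(2.0, log2_mu + shift) * lenfac
        for rep in range(1, cfg.n_replicates + 1):
            if cfg.dispersion > 0:
                lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
                cols[f"{group}_{rep}"] = rng.poisson(lam)
            else:
                cols[f"{group}_{rep}"] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=pd.Index(genes["gene_id"], name="gene_id"))
    return counts, lengths


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def plant_motifs(sequences: dict, truth: GroundTruth, pfm, cfg: SynthConfig) -> dict:
    """Write the motif consensus into a fraction of opened differential peaks.

    The consensus string (or its reverse complement, strand Bernoulli(0.5))
    is written at a uniform offset inside ``motif_plant_rate`` of the peaks
    planted with increased accessibility.  Occurrences are recorded in
    ``truth.motif_occurrences`` as (peak_id, offset, strand).  Returns a new
    sequences dict; the input is not modified.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_MOTIF)
    consensus = pfm.consensus
    L = len(consensus)
    opened = truth.peaks[truth.peaks["lfc"] > 0].reset_index(drop=True)
    min_w = int((truth.peaks["end"] - truth.peaks["start"]).min())
    if L >= min_w:
        raise ConfigError(f"motif length {L} >= minimum peak width {min_w}")
    out = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    occurrences = []
    if len(opened) and cfg.motif_plant_rate > 0:
        n_plant = int(round(cfg.motif_plant_rate * len(opened)))
        pick = rng.choice(len(opened), size=n_plant, replace=False)
        for i in sorted(int(j) for j in pick):
            r = opened.iloc[i]
            w = int(r["end"] - r["start"])
            offset = int(rng.integers(0, w - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else consensus.translate(_RC)[::-1]
            pos = int(r["start"]) + offset
            out[r["chrom"]][pos : pos + L] = word.encode()
            occurrences.append((r["peak_id"], offset, strand))
    truth.motif_occurrences = occurrences
    return {c: bytes(b).decode() for c, b in out.items()}


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A complete simulated study, ready to feed every pipeline stage."""

    cfg: SynthConfig
    annotation: GenomeAnnotation
    sequences: dict
    truth: GroundTruth
    fragments: dict  # (group, replicate) -> IntervalSet
    gene_counts: pd.DataFrame
    gene_lengths: pd.Series

    @property
    def sample_groups(self) -> dict:
        return {f"{g}_{r}": g for g, r in self.fragments}

    def fragments_by_sample(self) -> dict:
        return {f"{g}_{r}": fs for (g, r), fs in self.fragments.items()}


def default_pfms() -> list:
    """The toy position-frequency matrices bundled with the package."""
    from importlib.resources import files

    from .io import read_jaspar_pfm

    return read_jaspar_pfm(str(files("ocratlas").joinpath("data/toy_motifs.pfm")))


def simulate_study(cfg: SynthConfig | None = None, pfm=None) -> SyntheticStudy:
    """Run every simulation stage and return the assembled study."""
    cfg = cfg or SynthConfig()
    cfg.validate()
    annotation, sequences = simulate_genome(cfg)
    truth = simulate_peak_landscape(annotation, cfg)
    if pfm is None:
        matches = [p for p in default_pfms() if p.matrix_id == cfg.motif_id]
        if not matches:
            raise ConfigError(f"motif_id {cfg.motif_id!r} not among bundled motifs")
        pfm = matches[0]
    sequences = plant_motifs(sequences, truth, pfm, cfg)
    fragments = {
        (g, r): simulate_fragments(truth, g, r, cfg)
        for g in cfg.groups
        for r in range(1, cfg.n_replicates + 1)
    }
    counts, lengths = simulate_expression(annotation, truth, cfg)
    return SyntheticStudy(cfg, annotation, sequences, truth, fragments, counts, lengths)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study to disk as plain-text files.

    Produces genome.fa, annotation.gff3, chrom.sizes, fragments_<sample>.bed,
    gene_counts.tsv, gene_lengths.tsv and ground_truth.json.
    """
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(study.sequences, outdir / "genome.fa")
    _io.write_gff3(study.annotation, outdir / "annotation.gff3")
    _io.write_chrom_sizes(study.annotation.chrom_sizes, outdir / "chrom.sizes")
    for (g, r), frags in study.fragments.items():
        _io.write_bed(frags, outdir / f"fragments_{g}_{r}.bed", bed3=True)
    study.gene_counts.to_csv(outdir / "gene_counts.tsv", sep="\t")
    study.gene_lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    study.truth.to_json(outdir / "ground_truth.json")
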