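"""Synthetic embryo-style expression and ChIP data with planted truth.

The generator emulates the statistical structure of a multi-condition
knockdown experiment in early vertebrate embryos: maternal transcripts that
persist without new transcription, zygotically induced transcripts that
depend on one of three general initiation factors (TBP, TLF, TBP2), and a
TBP family-insensitive (TFI) class that is actively transcribed (hence
killed by the RNA polymerase II inhibitor alpha-amanitin) yet untouched by
any of the single knockdowns. A companion ChIP generator plants TF->gene
binding with designed peaks so the downstream filter/assignment chain can be
scored against known edges.

Everything is driven by one integer seed and is byte-deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io


class GeneClass(str, enum.Enum):
    MATERNAL_STABLE = "MATERNAL_STABLE"
    TBP_DEP = "TBP_DEP"
    TLF_DEP = "TLF_DEP"
    TBP2_DEP = "TBP2_DEP"
    TFI = "TFI"
    SILENT = "SILENT"


KD_CONDITION_OF_CLASS = {
    GeneClass.TBP_DEP: "tbp_as",
    GeneClass.TLF_DEP: "tlf_as",
    GeneClass.TBP2_DEP: "tbp2_as",
}
# classes whose stage-10.5 signal requires ongoing RNAPII transcription
ZYGOTIC_CLASSES = (GeneClass.TBP_DEP, GeneClass.TLF_DEP,
                   GeneClass.TBP2_DEP, GeneClass.TFI)

DEFAULT_PROPORTIONS = {
    GeneClass.MATERNAL_STABLE: 0.40,
    GeneClass.TBP_DEP: 0.10,
    GeneClass.TLF_DEP: 0.10,
    GeneClass.TBP2_DEP: 0.10,
    GeneClass.TFI: 0.10,
    GeneClass.SILENT: 0.20,
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic experiment.

    Effect sizes are log2 units. ``amanitin_residual`` is the fraction of
    control signal remaining for actively transcribed classes after RNAPII
    inhibition (qPCR-style "<5% of control"). ``probe_sd`` is per-probe
    log2 noise; 0 gives the closed-form noise-free limit.
    """

    n_genes: int = 1000
    probes_per_transcript: int = 11
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    induction_lfc: float = 3.0
    knockdown_lfc: float = -3.0
    amanitin_residual: float = 0.05
    probe_sd: float = 0.25
    probe_affinity_sd: float = 0.5
    nb_dispersion: float = 0.1
    seq_depth: float = 5e5
    maternal_log2: float = 9.0
    zygotic_base_log2: float = 7.0
    silent_log2: float = 4.0
    base_log2_sd: float = 0.7
    seed: int = 0

    def __post_init__(self):
        fr = np.array(list(self.class_proportions.values()), float)
        if (fr < 0).any() or (fr > 1).any() or abs(fr.sum() - 1) > 1e-9:
            raise ValueError("class proportions must be in [0,1] and sum to 1")
        if self.probe_sd < 0:
            raise ValueError("probe_sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene class, TF regulators, base levels."""

    gene_classes: pd.Series  # gene -> GeneClass value (str)
    base_log2: pd.Series  # gene -> stage-10.5 control log2 level
    regulators: dict[str, set[str]] = field(default_factory=dict)  # gene -> TFs
    tfs: list[str] = field(default_factory=list)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(tf, g) for g, tfs in self.regulators.items() for tf in tfs}

    def to_json_dict(self) -> dict:
        return {
            "gene_classes": self.gene_classes.to_dict(),
            "base_log2": {g: float(v) for g, v in self.base_log2.items()},
            "regulators": {g: sorted(t) for g, t in self.regulators.items()},
            "tfs": list(self.tfs),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(pd.Series(d["gene_classes"]),
                   pd.Series(d["base_log2"], dtype=float),
                   {g: set(t) for g, t in d["regulators"].items()},
                   list(d["tfs"]))


def make_default_design() -> pd.DataFrame:
    """Sample sheet: stage 7 control plus five stage-10.5 conditions, 2 reps."""
    rows = []
    for cond, stage in [("control", "st7"), ("control", "st10.5"),
                        ("tbp_as", "st10.5"), ("tlf_as", "st10.5"),
                        ("tbp2_as", "st10.5"), ("amanitin", "st10.5")]:
        for rep in (1, 2):
            rows.append({"sample": f"{stage}_{cond}_r{rep}",
                         "stage": stage, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows)


def make_count_design(n_reps: int = 2) -> pd.DataFrame:
    rows = [{"sample": f"st10.5_{cond}_r{r}", "stage": "st10.5",
             "condition": cond, "replicate": r}
            for cond in ("control", "tkd") for r in range(1, n_reps + 1)]
    return pd.DataFrame(rows)


def design_samples(design: pd.DataFrame, stage: str, condition: str) -> list[str]:
    sel = design[(design["stage"] == stage) & (design["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"design has no samples for {stage}/{condition}")
    return list(sel.sort_values("replicate")["sample"])


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def generate_annotation(n_chrom: int, chrom_length: int, n_genes: int,
                        seed: int, min_gap: int = 2000,
                        gene_length: tuple[int, int] = (2000, 8000)
                        ) -> pd.DataFrame:
    """Place stranded, non-overlapping gene bodies on ``n_chrom`` chromosomes.

    Genes are spaced by at least ``min_gap`` bp; raises if the requested
    genes cannot fit. Coordinates are 0-based half-open BED.
    """
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    max_len = gene_length[1]
    for n_c in per_chrom:
        if n_c * (max_len + min_gap) + min_gap > chrom_length:
            raise ValueError(
                f"cannot pack {n_c} genes of up to {max_len} bp with "
                f"{min_gap} bp gaps into a {chrom_length} bp chromosome")
    records = []
    gi = 0
    for ci, n_c in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        lengths = rng.integers(gene_length[0], max_len + 1, size=n_c)
        slack = chrom_length - int(lengths.sum()) - min_gap * (n_c + 1)
        # distribute leftover space as random extra gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n_c + 1))
        extra = np.diff(np.concatenate([[0], cuts]))
        pos = min_gap + extra[0]
        for j in range(n_c):
            start = int(pos)
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            records.append({"chrom": chrom, "start": start, "end": end,
                            "name": f"g{gi:05d}", "score": 0.0,
                            "strand": strand})
            pos = end + min_gap + extra[j + 1] if j + 1 < len(extra) else end
            gi += 1
    return pd.DataFrame(records, columns=io.BED_COLUMNS)


# ---------------------------------------------------------------------------
# expression (probe-level) experiment
# ---------------------------------------------------------------------------

def _assign_classes(cfg: SimConfig, rng) -> pd.Series:
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    classes = list(cfg.class_proportions)
    counts = np.floor(np.array([cfg.class_proportions[c] for c in classes])
                      * cfg.n_genes).astype(int)
    # top up rounding shortfall deterministically
    i = 0
    while counts.sum() < cfg.n_genes:
        counts[i % len(counts)] += 1
        i += 1
    labels = np.repeat([GeneClass(c).value for c in classes], counts)
    rng.shuffle(labels)
    return pd.Series(labels, index=genes, name="gene_class")


def expected_log2(cfg: SimConfig, gene_class: str, base: float,
                  stage: str, condition: str) -> float:
    """Closed-form expected log2 signal for one gene in one design cell.

    ``base`` is the gene's stage-10.5 control level. Zygotic classes sit at
    ``base - induction_lfc`` at stage 7; knockdown shifts apply only to the
    matching dependent class; amanitin multiplies all actively transcribed
    classes by the residual fraction; SILENT genes stay at the silent floor.
    """
    gc = GeneClass(gene_class)
    if gc is GeneClass.SILENT:
        return base
    if gc is GeneClass.MATERNAL_STABLE:
        return base
    level = base - cfg.induction_lfc if stage == "st7" else base
    if stage == "st7":
        return level
    if condition == "amanitin":
        return base + np.log2(cfg.amanitin_residual)
    if condition == KD_CONDITION_OF_CLASS.get(gc):
        return base + cfg.knockdown_lfc
    return base


def generate_expression_experiment(cfg: SimConfig,
                                   design: pd.DataFrame | None = None
                                   ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Simulate probe-level intensities for the full sample design.

    Returns ``(probe_values, probe_map, truth)``: a probes x samples matrix
    of linear intensities, the probe -> transcript map, and the planted
    truth. Probe affinity offsets are drawn once per probe and shared across
    samples, so paired probe differences cancel them.
    """
    design = make_default_design() if design is None else design
    for stage, cond in [("st7", "control"), ("st10.5", "control"),
                        ("st10.5", "tbp_as"), ("st10.5", "tlf_as"),
                        ("st10.5", "tbp2_as"), ("st10.5", "amanitin")]:
        design_samples(design, stage, cond)  # raises on a missing cell
    rng = np.random.default_rng(cfg.seed)
    classes = _assign_classes(cfg, rng)
    genes = classes.index
    base = pd.Series(np.where(
        classes == GeneClass.MATERNAL_STABLE.value,
        rng.normal(cfg.maternal_log2, cfg.base_log2_sd, cfg.n_genes),
        np.where(classes == GeneClass.SILENT.value,
                 cfg.silent_log2,
                 rng.normal(cfg.zygotic_base_log2 + cfg.induction_lfc,
                            cfg.base_log2_sd, cfg.n_genes))),
        index=genes, name="base_log2")

    n_probes = cfg.probes_per_transcript
    probe_ids = [f"{g}_p{j:02d}" for g in genes for j in range(n_probes)]
    probe_map = pd.Series(np.repeat(genes.to_numpy(), n_probes),
                          index=probe_ids, name="transcript_id")
    affinity = rng.normal(0.0, cfg.probe_affinity_sd, len(probe_ids))

    cols = {}
    for _, row in design.iterrows():
        mean_log2 = np.array([
            expected_log2(cfg, classes[g], base[g], row["stage"],
                          row["condition"]) for g in genes])
        per_probe = np.repeat(mean_log2, n_probes) + affinity
        noise = (rng.normal(0.0, cfg.probe_sd, len(probe_ids))
                 if cfg.probe_sd > 0 else 0.0)
        cols[row["sample"]] = np.exp2(per_probe + noise)
    probe_values = pd.DataFrame(cols, index=probe_ids)
    truth = SyntheticTruth(classes, base)
    return probe_values, probe_map, truth


# ---------------------------------------------------------------------------
# count (RNA-seq-like) experiment
# ---------------------------------------------------------------------------

def generate_count_experiment(cfg: SimConfig, design: pd.DataFrame,
                              truth: SyntheticTruth) -> pd.DataFrame:
    """Simulate a genes x samples NB count matrix for control vs TKD.

    The triple knockdown applies the union of the three single-knockdown
    effects: every dependent class is shifted by ``knockdown_lfc``; TFI and
    maternal genes are unchanged. Counts are NB with the configured
    dispersion (0 collapses to Poisson) at a depth-scaled mean.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    classes = truth.gene_classes
    base = truth.base_log2
    dep = classes.isin([c.value for c in KD_CONDITION_OF_CLASS])
    cols = {}
    for _, row in design.iterrows():
        if row["condition"] not in ("control", "tkd"):
            raise ValueError(f"unexpected count condition {row['condition']}")
        log2_level = base.to_numpy(float).copy()
        if row["condition"] == "tkd":
            log2_level[dep.to_numpy()] += cfg.knockdown_lfc
        rel = np.exp2(log2_level)
        mu = cfg.seq_depth * rel / rel.sum()
        if cfg.nb_dispersion <= 0:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape=size, scale=mu / size)
            counts = rng.poisson(lam)
        cols[row["sample"]] = counts
    return pd.DataFrame(cols, index=classes.index)


# ---------------------------------------------------------------------------
# ChIP experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFSpec:
    """One TF's planted binding: its encoding gene and its target genes."""

    gene: str
    targets: tuple[str, ...]


@dataclass(frozen=True)
class ChipConfig:
    peak_width: int = 400
    read_length: int = 50
    n_decoy_peaks: int = 20
    background_reads: int = 50_000  # per track, uniform over the genome
    enrichment: float = 10.0  # fold extra reads at a true peak
    decoy_enrichment: float = 0.5  # chip coverage at a decoy, vs input


def generate_chip_experiment(annotation: pd.DataFrame,
                             tf_specs: dict[str, TFSpec],
                             seed: int,
                             chip_cfg: ChipConfig | None = None
                             ) -> tuple[dict[str, pd.DataFrame],
                                        dict[str, pd.DataFrame],
                                        pd.DataFrame,
                                        SyntheticTruth]:
    """Simulate per-TF peak and read tracks plus a matched input track.

    True peaks are centred on each target gene's TSS (inside its basal
    regulatory domain); decoy peaks land anywhere with reads at background
    level, so the input-percentile RPKM filter removes them. Returns
    ``(peaks_by_tf, reads_by_tf, input_reads, truth)`` with truth carrying
    the planted edge set.
    """
    if len(tf_specs) < 1:
        raise ValueError("need at least one TF spec")
    cc = chip_cfg or ChipConfig()
    known = set(annotation["name"])
    for tf, spec in tf_specs.items():
        missing = ({spec.gene} | set(spec.targets)) - known
        if missing:
            raise ValueError(f"TF {tf} references unknown genes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("name")
    chrom_len = annotation.groupby("chrom")["end"].max() + 10_000
    chroms = list(chrom_len.index)
    sizes = chrom_len.to_numpy(float)
    probs = sizes / sizes.sum()

    def uniform_reads(n: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=probs)
        starts = (rng.random(n) * (sizes[ci] - cc.read_length)).astype(int)
        df = pd.DataFrame({"chrom": [chroms[i] for i in ci], "start": starts,
                           "end": starts + cc.read_length, "name": ".",
                           "score": 0.0, "strand": "+"})
        return df.sort_values(["chrom", "start"], kind="stable",
                              ignore_index=True)

    def tss_of(gene: str) -> tuple[str, int]:
        row = ann.loc[gene]
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"])
        return str(row["chrom"]), tss

    input_reads = uniform_reads(cc.background_reads)
    peaks_by_tf: dict[str, pd.DataFrame] = {}
    reads_by_tf: dict[str, pd.DataFrame] = {}
    regulators: dict[str, set[str]] = {}
    half = cc.peak_width // 2
    for tf, spec in tf_specs.items():
        peak_rows = []
        extra_reads = []
        for target in spec.targets:
            chrom, tss = tss_of(target)
            start = max(0, tss - half)
            peak_rows.append({"chrom": chrom, "start": start,
                              "end": start + cc.peak_width,
                              "name": f"{tf}_{target}", "score": 1.0,
                              "strand": "."})
            regulators.setdefault(target, set()).add(tf)
            # enriched reads on top of background within the peak
            lam = cc.enrichment * cc.background_reads * cc.peak_width / sizes.sum()
            n_extra = rng.poisson(lam)
            offs = (rng.random(n_extra) * (cc.peak_width - cc.read_length)
                    ).astype(int)
            for o in offs:
                extra_reads.append({"chrom": chrom, "start": start + int(o),
                                    "end": start + int(o) + cc.read_length,
                                    "name": ".", "score": 0.0, "strand": "+"})
        decoy_rows = []
        for d in range(cc.n_decoy_peaks):
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.random() * (sizes[ci] - cc.peak_width))
            decoy_rows.append({"chrom": chroms[ci], "start": start,
                               "end": start + cc.peak_width,
                               "name": f"{tf}_decoy{d:02d}", "score": 0.5,
                               "strand": "."})
        peak_rows.extend(decoy_rows)
        background = uniform_reads(cc.background_reads)
        if decoy_rows and cc.decoy_enrichment < 1.0:
            # thin chip background over decoy regions so decoys sit below
            # the input level and the percentile filter removes them
            from .intervals import count_overlaps
            dec = pd.DataFrame(decoy_rows)
            in_decoy = count_overlaps(background, dec) > 0
            drop = in_decoy & (rng.random(len(background))
                               > cc.decoy_enrichment)
            background = background.loc[~drop].reset_index(drop=True)
        chip = pd.concat([background,
                          pd.DataFrame(extra_reads, columns=io.BED_COLUMNS)],
                         ignore_index=True)
        reads_by_tf[tf] = chip.sort_values(["chrom", "start"], kind="stable",
                                           ignore_index=True)
        peaks_by_tf[tf] = pd.DataFrame(peak_rows, columns=io.BED_COLUMNS)

    classes = pd.Series("SILENT", index=annotation["name"], name="gene_class")
    truth = SyntheticTruth(classes, pd.Series(0.0, index=classes.index),
                           regulators, list(tf_specs))
    return peaks_by_tf, reads_by_tf, input_reads, truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_experiment(outdir, probe_values, probe_map, truth,
                     counts=None, annotation=None) -> None:
    """Write generator outputs as plain-text files under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_matrix_tsv(probe_values, out / "probes.tsv", index_label="probe_id")
    probe_map.rename("transcript_id").to_csv(out / "probe_map.tsv", sep="\t",
                                             index_label="probe_id")
    io.write_json(truth.to_json_dict(), out / "truth.json")
    if counts is not None:
        io.write_matrix_tsv(counts, out / "counts.tsv", index_label="gene_id")
    if annotation is not None:
        io.write_bed(annotation, out / "genes.bed")
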