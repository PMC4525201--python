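"""Synthetic RNA-seq count data with planted selection structure.

Generates a chicken-style study design — two sexes, several tissues, a few
biological replicates — of negative-binomially distributed per-gene read
counts, for autosomal and Z-linked genes, the latter assigned to three
evolutionary strata.  Per-gene latent selection strengths set the
negative-binomial dispersion (stronger selection -> lower biological
coefficient of variation), and the degree of dosage compensation of Z
genes is linked to the selection axes through planted regression
coefficients, so the analysis pipeline's estimates can be checked against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyDesign",
    "TruthConfig",
    "CountMatrix",
    "SyntheticDataset",
    "generate",
    "write_dataset",
    "read_dataset",
]

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the study: tissues, replication, gene classes."""

    tissues: tuple[str, ...] = ("gonad", "heart", "liver")
    n_replicates: int = 4
    n_autosomal: int = 2000
    n_z: int = 450
    #: fraction of Z genes in each stratum (oldest first)
    strata_props: tuple[float, ...] = (0.45, 0.30, 0.25)
    #: stratum ages in My (midpoints of the divergence-window estimates)
    strata_ages: tuple[float, ...] = (90.5, 58.0, 52.0)
    #: mean library size (reads); default emulates deep libraries scaled
    #: down 100x so tests stay fast
    mean_libsize: float = 160_000.0
    libsize_sigma: float = 0.15
    #: log-normal gene-length distribution (log2 scale, bp)
    length_log2_mean: float = 10.5
    length_log2_sd: float = 0.8
    #: fraction of gene-tissue pairs planted below the expression filter
    low_expressed_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group to estimate BCV")
        if len(self.strata_props) != len(self.strata_ages):
            raise ValueError("strata_props and strata_ages must align")
        if abs(sum(self.strata_props) - 1.0) > 1e-9:
            raise ValueError("strata_props must sum to 1")


@dataclass(frozen=True)
class TruthConfig:
    """Planted ground truth linking selection, dispersion and compensation.

    log2 BCV of each sex is an affine decreasing function of that sex's
    latent selection strength; the male:female expression ratio of Z genes
    is a linear function of the true selection axes (concordant strength
    and male bias) plus noise.
    """

    # latent selection strengths: shared and sex-difference components
    sel_shared_low: float = 0.2
    sel_shared_high: float = 3.2
    sel_diff_sd: float = 1.5
    # affine selection -> log2 BCV link
    bcv_log2_intercept: float = -0.4
    bcv_log2_slope: float = 0.8
    bcv_log2_noise: float = 0.05
    #: multiplier on female NB dispersion (>1 emulates noisier female expression)
    female_dispersion_factor: float = 1.3
    # planted Z-gene log2(M:F) ratio coefficients on the (centered) true axes;
    # defaults are the liver-like regime: compensation improves with concordant
    # selection, worsens with male-biased selection, and the male-bias effect
    # is damped where concordant selection is strong
    ratio_intercept: float = 0.5
    ratio_concordant: float = -0.25
    ratio_male_bias: float = 0.25
    ratio_interaction: float = -0.4
    ratio_noise: float = 0.1
    #: per-10-My effect of stratum age on the ratio (0 = no age effect)
    stratum_age_effect: float = 0.0
    #: sd of planted autosomal sex bias (0 = unbiased autosomes)
    autosomal_bias_sd: float = 0.0
    # baseline expression
    base_log2_rpkm_mean: float = 5.0
    base_log2_rpkm_sd: float = 1.5
    tissue_effect_sd: float = 0.5


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus complete sample metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample; columns: sex, tissue, replicate
    annotation: pd.DataFrame  # index: gene_id; chrom, length, stratum, stratum_age

    def __post_init__(self) -> None:
        if not (self.counts.to_numpy() >= 0).all():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("sex", "tissue", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")


@dataclass
class SyntheticDataset:
    cm: CountMatrix
    truth: pd.DataFrame  # per gene x tissue ground truth


def _sample_names(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for tissue in design.tissues:
        for sex in ("M", "F"):
            for rep in range(1, design.n_replicates + 1):
                rows.append((f"{tissue}_{sex}{rep}", sex, tissue, rep))
    df = pd.DataFrame(rows, columns=["sample", "sex", "tissue", "replicate"])
    return df.set_index("sample")


def generate(
    design: StudyDesign = StudyDesign(),
    truth_config: TruthConfig = TruthConfig(),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset.

    Counts are drawn NB with mean = true RPKM x gene length (kb) x library
    size (millions) and per-gene/sex/tissue dispersion from the planted
    truth.  Identical seeds give bit-identical output.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    tc = truth_config
    n_genes = design.n_autosomal + design.n_z

    gene_ids = np.array(
        [f"gA{i:05d}" for i in range(design.n_autosomal)]
        + [f"gZ{i:05d}" for i in range(design.n_z)]
    )
    is_z = np.zeros(n_genes, dtype=bool)
    is_z[design.n_autosomal:] = True

    # annotation
    chrom = np.where(is_z, "Z", "A")
    lengths = np.round(
        2.0 ** rng.normal(design.length_log2_mean, design.length_log2_sd, n_genes)
    ).astype(int)
    lengths = np.clip(lengths, 200, None)
    n_strata = len(design.strata_props)
    strata = np.zeros(n_genes, dtype=int)  # 0 = autosomal / unassigned
    counts_per_stratum = rng.multinomial(design.n_z, design.strata_props)
    stratum_labels = np.repeat(np.arange(1, n_strata + 1), counts_per_stratum)
    strata[design.n_autosomal:] = rng.permutation(stratum_labels)
    ages = np.zeros(n_genes)
    ages[is_z] = np.asarray(design.strata_ages)[strata[is_z] - 1]
    annot = pd.DataFrame(
        {
            "chrom": chrom,
            "length": lengths,
            "stratum": strata,
            "stratum_age": ages,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    samples = _sample_names(design)
    libsizes = design.mean_libsize * np.exp(
        rng.normal(-0.5 * design.libsize_sigma**2, design.libsize_sigma, len(samples))
    )
    samples = samples.assign(libsize=np.round(libsizes).astype(int))

    # per gene x tissue latent truth
    truth_rows = []
    count_blocks = []
    base_gene = rng.normal(tc.base_log2_rpkm_mean, tc.base_log2_rpkm_sd, n_genes)
    mean_age = float(np.mean(design.strata_ages))
    for tissue in design.tissues:
        sel_shared = rng.uniform(tc.sel_shared_low, tc.sel_shared_high, n_genes)
        sel_diff = rng.normal(0.0, tc.sel_diff_sd, n_genes)
        sel_m = sel_shared + 0.5 * sel_diff
        sel_f = sel_shared - 0.5 * sel_diff
        l2bcv_m = (
            tc.bcv_log2_intercept
            - tc.bcv_log2_slope * sel_m
            + rng.normal(0.0, tc.bcv_log2_noise, n_genes)
        )
        l2bcv_f = (
            tc.bcv_log2_intercept
            - tc.bcv_log2_slope * sel_f
            + rng.normal(0.0, tc.bcv_log2_noise, n_genes)
        )
        disp_m = (2.0**l2bcv_m) ** 2
        disp_f = (2.0**l2bcv_f) ** 2 * tc.female_dispersion_factor
        l2bcv_f_real = 0.5 * np.log2(disp_f)
        concordant = -(l2bcv_m + l2bcv_f_real) / SQRT2
        male_bias = (l2bcv_f_real - l2bcv_m) / SQRT2

        ratio = np.zeros(n_genes)
        if tc.autosomal_bias_sd > 0:
            ratio[~is_z] = rng.normal(0.0, tc.autosomal_bias_sd, (~is_z).sum())
        if is_z.any():
            # plant the link on axes centered at the Z-gene mean, so main
            # effects are effects at a typical gene and the interaction is
            # identifiable
            zc = concordant[is_z] - concordant[is_z].mean()
            zb = male_bias[is_z] - male_bias[is_z].mean()
            ratio[is_z] = (
                tc.ratio_intercept
                + tc.ratio_concordant * zc
                + tc.ratio_male_bias * zb
                + tc.ratio_interaction * zc * zb
                + tc.stratum_age_effect * (ages[is_z] - mean_age) / 10.0
                + rng.normal(0.0, tc.ratio_noise, int(is_z.sum()))
            )

        base = base_gene + rng.normal(0.0, tc.tissue_effect_sd, n_genes)
        low = rng.random(n_genes) < design.low_expressed_frac
        rpkm_base = 2.0**base
        rpkm_base[low] = rng.uniform(0.2, 1.9, int(low.sum()))
        rpkm_m = rpkm_base * 2.0 ** (0.5 * ratio)
        rpkm_f = rpkm_base * 2.0 ** (-0.5 * ratio)

        tis_samples = samples[samples["tissue"] == tissue]
        block = np.empty((n_genes, len(tis_samples)), dtype=np.int64)
        for j, (name, row) in enumerate(tis_samples.iterrows()):
            rpkm = rpkm_m if row["sex"] == "M" else rpkm_f
            disp = disp_m if row["sex"] == "M" else disp_f
            mean = rpkm * (lengths / 1000.0) * (row["libsize"] / 1e6)
            n_nb = 1.0 / disp
            p_nb = n_nb / (n_nb + mean)
            block[:, j] = rng.negative_binomial(n_nb, p_nb)
        count_blocks.append(
            pd.DataFrame(block, index=annot.index, columns=tis_samples.index)
        )

        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "tissue": tissue,
                    "sel_m": sel_m,
                    "sel_f": sel_f,
                    "log2_bcv_m": l2bcv_m,
                    "log2_bcv_f": l2bcv_f_real,
                    "concordant": concordant,
                    "male_bias": male_bias,
                    "log2_mf_ratio": ratio,
                    "base_rpkm": rpkm_base,
                }
            )
        )

    counts = pd.concat(count_blocks, axis=1)[samples.index]
    truth = pd.concat(truth_rows, ignore_index=True)
    cm = CountMatrix(counts=counts, samples=samples, annotation=annot)
    return SyntheticDataset(cm=cm, truth=truth)


# -- disk round trip --------------------------------------------------------


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts / annotation / sample sheet / truth as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    try:
        ds.cm.counts.to_csv(paths["counts"], sep="\t")
        ds.cm.annotation.to_csv(paths["annotation"], sep="\t")
        ds.cm.samples.to_csv(paths["samples"], sep="\t")
        ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return paths


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(d / "annotation.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    counts.columns.name = samples.index.name
    truth_path = d / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    )
    cm = CountMatrix(counts=counts, samples=samples, annotation=annotation)
    return SyntheticDataset(cm=cm, truth=truth)


# -- config file ------------------------------------------------------------


def load_config(path: str | Path) -> tuple[StudyDesign, TruthConfig]:
    """Read a YAML config with optional ``design`` and ``truth`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    design_kw = raw.get("design", {}) or {}
    for key in ("tissues", "strata_props", "strata_ages"):
        if key in design_kw:
            design_kw[key] = tuple(design_kw[key])
    truth_kw = raw.get("truth", {}) or {}
    return StudyDesign(**design_kw), TruthConfig(**truth_kw)


def dump_config(design: StudyDesign, truth: TruthConfig, path: str | Path) -> None:
    data = {"design": asdict(design), "truth": asdict(truth)}
    data["design"]["tissues"] = list(design.tissues)
    data["design"]["strata_props"] = list(design.strata_props)
    data["design"]["strata_ages"] = list(design.strata_ages)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
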