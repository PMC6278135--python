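"""Synthetic posterior-fossa ependymoma cohort generator.

Emulates the data a 450K-style methylation study produces, at reduced probe
count: a beta-value matrix with CpG-island marker probes separating the PFA
(CpG-island hypermethylated) and PFB subgroups, per-probe methylated and
unmethylated intensity channels carrying arm-level copy-number signal,
a three-gene (CRIP1, DRD4, LBX2) pyrosequencing panel with per-class beta
distributions, and an H3K27me3 immunohistochemistry percent-labeled value
per tumor.

The intensity model is multiplicative: the total signal of a probe is
log-normal around ``base_intensity`` scaled by ``2**gain_log2_shift`` on
gained arms, and the methylated fraction of the total equals the sample's
beta value, so beta == meth / (meth + unmeth) exactly (offset 0).

One top-level seed drives a :class:`numpy.random.SeedSequence`; each data
block (sample sheet, beta matrix, intensities, gene panel, IHC) draws from
its own spawned child stream, so adding a block never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import GENES
from .errors import ConfigurationError

SUBGROUPS = ("PFA", "PFB")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS = ("chrX", "chrY")
#: autosomal arms in karyotype order; probes are dealt round-robin across them
AUTOSOMAL_ARMS = tuple(f"{i}{a}" for i in range(1, 23) for a in ("p", "q"))

_DEFAULT_GENE_PANEL = {
    gene: {"PFA": (8.0, 6.0), "PFB": (1.0, 15.0)} for gene in GENES
}
# (weight, low, high) uniform mixture components of percent-labeled nuclei,
# mirroring the observed IHC categories: PFA always <= 50%, most PFB > 80%
# with a minority labeled in only 10-60% of cells.
_DEFAULT_IHC = {
    "PFA": ((0.38, 0.0, 5.0), (0.62, 5.0, 50.0)),
    "PFB": ((0.867, 81.0, 100.0), (0.133, 10.0, 60.0)),
}


def _check_shape(name: str, pair) -> tuple[float, float]:
    try:
        a, b = float(pair[0]), float(pair[1])
    except (TypeError, ValueError, IndexError):
        raise ConfigurationError(f"{name}: expected an (alpha, beta) pair, got {pair!r}")
    if not (a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b)):
        raise ConfigurationError(f"{name}: shape parameters must be finite and > 0, got {pair!r}")
    return a, b


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the emulated study: 45 PFA and 15 PFB posterior-fossa
    tumors with six normal cerebellum references, a scaled-down array of
    2000 probes of which 100 sit on sex chromosomes and 400 on CpG islands
    (40 of those separating the subgroups), and well-separated per-class
    beta distributions for both the marker probes and the gene panel.
    """

    n_pfa: int = 45
    n_pfb: int = 15
    n_controls: int = 6
    n_probes_total: int = 2000
    n_sex_probes: int = 100
    n_island_probes: int = 400
    n_marker_probes: int = 40
    pfa_marker_beta: tuple[float, float] = (8.0, 6.0)
    pfb_marker_beta: tuple[float, float] = (1.0, 15.0)
    background_beta: tuple[float, float] = (5.0, 5.0)
    gene_panel_dists: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_GENE_PANEL
    )
    frac_pfa_1q_gain: float = 0.3
    gain_log2_shift: float = 0.5
    base_intensity: float = 2000.0
    intensity_noise_sd: float = 0.1
    ihc_dists: Mapping[str, Sequence[tuple[float, float, float]]] = field(
        default_factory=lambda: _DEFAULT_IHC
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pfa", "n_pfb", "n_controls", "n_probes_total",
                     "n_sex_probes", "n_island_probes", "n_marker_probes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name}: must be a non-negative integer, got {v!r}")
        if self.n_sex_probes + self.n_island_probes > self.n_probes_total:
            raise ConfigurationError(
                "n_sex_probes + n_island_probes exceeds n_probes_total "
                f"({self.n_sex_probes} + {self.n_island_probes} > {self.n_probes_total})"
            )
        if self.n_marker_probes > self.n_island_probes:
            raise ConfigurationError(
                f"n_marker_probes ({self.n_marker_probes}) exceeds "
                f"n_island_probes ({self.n_island_probes})"
            )
        _check_shape("pfa_marker_beta", self.pfa_marker_beta)
        _check_shape("pfb_marker_beta", self.pfb_marker_beta)
        _check_shape("background_beta", self.background_beta)
        for gene in GENES:
            if gene not in self.gene_panel_dists:
                raise ConfigurationError(f"gene_panel_dists: missing gene {gene}")
            for cls in SUBGROUPS:
                _check_shape(f"gene_panel_dists[{gene}][{cls}]",
                             self.gene_panel_dists[gene][cls])
        if not 0.0 <= self.frac_pfa_1q_gain <= 1.0:
            raise ConfigurationError(
                f"frac_pfa_1q_gain: must be in [0, 1], got {self.frac_pfa_1q_gain!r}")
        if not self.base_intensity > 0:
            raise ConfigurationError(f"base_intensity: must be > 0, got {self.base_intensity!r}")
        if not self.intensity_noise_sd >= 0:
            raise ConfigurationError(
                f"intensity_noise_sd: must be >= 0, got {self.intensity_noise_sd!r}")
        for cls in SUBGROUPS:
            if cls not in self.ihc_dists:
                raise ConfigurationError(f"ihc_dists: missing class {cls}")
            comps = self.ihc_dists[cls]
            w = sum(c[0] for c in comps)
            if not np.isclose(w, 1.0, atol=1e-6):
                raise ConfigurationError(f"ihc_dists[{cls}]: weights sum to {w}, not 1")
            for weight, lo, hi in comps:
                if weight < 0 or not (0 <= lo <= hi <= 100):
                    raise ConfigurationError(
                        f"ihc_dists[{cls}]: bad component ({weight}, {lo}, {hi})")


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground truth.

    ``beta`` and the two intensity frames are probes x samples with probe
    ids as index and sample ids as columns; ``annotation`` has one row per
    probe (probe_id, chrom, pos, arm, cpg_island); the sample sheet records
    the true subgroup and 1q-gain state of every sample.
    """

    config: CohortConfig
    sample_sheet: pd.DataFrame
    beta: pd.DataFrame
    annotation: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    gene_panel: pd.DataFrame
    ihc: pd.DataFrame

    @property
    def marker_probe_ids(self) -> list[str]:
        """Probes planted to separate PFA from PFB (ground truth)."""
        ann = self.annotation
        return list(ann.loc[ann["is_marker"] == 1, "probe_id"])


def _build_annotation(config: CohortConfig) -> pd.DataFrame:
    n_auto = config.n_probes_total - config.n_sex_probes
    arms = np.empty(config.n_probes_total, dtype=object)
    # autosomal probes dealt round-robin across arms so every arm is covered
    for i in range(n_auto):
        arms[i] = AUTOSOMAL_ARMS[i % len(AUTOSOMAL_ARMS)]
    for j in range(config.n_sex_probes):
        arms[n_auto + j] = ("Xp", "Xq", "Yp", "Yq")[j % 4]
    chrom = np.array([f"chr{a[:-1]}" for a in arms], dtype=object) if len(arms) else np.array([], dtype=object)
    # positions: running 1-based offset within each arm
    pos = np.zeros(config.n_probes_total, dtype=int)
    counters: dict[str, int] = {}
    for i, a in enumerate(arms):
        counters[a] = counters.get(a, 0) + 1
        pos[i] = counters[a] * 1000
    island = np.zeros(config.n_probes_total, dtype=int)
    island[: config.n_island_probes] = 1  # islands are autosomal by construction
    marker = np.zeros(config.n_probes_total, dtype=int)
    marker[: config.n_marker_probes] = 1
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:07d}" for i in range(config.n_probes_total)],
            "chrom": chrom,
            "pos": pos,
            "arm": arms,
            "cpg_island": island,
            "is_marker": marker,
        }
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; identical config + seed gives an identical cohort."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_samples, rng_beta, rng_intensity, rng_panel, rng_ihc = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    annotation = _build_annotation(config)
    probe_ids = annotation["probe_id"].to_numpy()

    n_tumor = config.n_pfa + config.n_pfb
    sample_ids = (
        [f"PFA_{i:03d}" for i in range(config.n_pfa)]
        + [f"PFB_{i:03d}" for i in range(config.n_pfb)]
        + [f"CTRL_{i:03d}" for i in range(config.n_controls)]
    )
    subgroup = (["PFA"] * config.n_pfa + ["PFB"] * config.n_pfb
                + ["CONTROL"] * config.n_controls)
    # clinical flavor only: PFA median ~4 y, PFB median ~30 y
    ages = np.concatenate([
        np.round(np.exp(rng_samples.normal(np.log(4.0), 0.8, config.n_pfa))),
        np.round(np.exp(rng_samples.normal(np.log(30.0), 0.5, config.n_pfb))),
        np.round(np.exp(rng_samples.normal(np.log(40.0), 0.3, config.n_controls))),
    ]).astype(int) if sample_ids else np.array([], dtype=int)
    gain = np.zeros(len(sample_ids), dtype=bool)
    gain[: config.n_pfa] = rng_samples.random(config.n_pfa) < config.frac_pfa_1q_gain
    sample_sheet = pd.DataFrame(
        {"sample_id": sample_ids, "subgroup": subgroup, "age": ages, "has_1q_gain": gain}
    )

    n_probes, n_samples = config.n_probes_total, len(sample_ids)
    a_bg, b_bg = config.background_beta
    beta_vals = rng_beta.beta(a_bg, b_bg, size=(n_probes, n_samples)) if n_probes * n_samples else np.zeros((n_probes, n_samples))
    nm = config.n_marker_probes
    if nm and config.n_pfa:
        a, b = config.pfa_marker_beta
        beta_vals[:nm, : config.n_pfa] = rng_beta.beta(a, b, size=(nm, config.n_pfa))
    if nm and config.n_pfb:
        a, b = config.pfb_marker_beta
        beta_vals[:nm, config.n_pfa: n_tumor] = rng_beta.beta(a, b, size=(nm, config.n_pfb))
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)

    # total intensity: log-normal around base * 2**shift on gained-arm probes
    log_mu = np.full((n_probes, n_samples), np.log(config.base_intensity))
    on_1q = (annotation["arm"] == "1q").to_numpy()
    if on_1q.any() and gain.any():
        log_mu[np.ix_(on_1q, gain)] += config.gain_log2_shift * np.log(2.0)
    total = np.exp(rng_intensity.normal(log_mu, config.intensity_noise_sd)) if n_probes * n_samples else np.zeros_like(log_mu)
    meth = pd.DataFrame(beta_vals * total, index=probe_ids, columns=sample_ids)
    unmeth = pd.DataFrame((1.0 - beta_vals) * total, index=probe_ids, columns=sample_ids)

    tumor_ids = sample_ids[:n_tumor]
    panel = {"sample_id": tumor_ids}
    for gene in GENES:
        a_pfa, b_pfa = config.gene_panel_dists[gene]["PFA"]
        a_pfb, b_pfb = config.gene_panel_dists[gene]["PFB"]
        panel[gene] = np.concatenate([
            100.0 * rng_panel.beta(a_pfa, b_pfa, config.n_pfa),
            100.0 * rng_panel.beta(a_pfb, b_pfb, config.n_pfb),
        ]) if n_tumor else np.array([])
    panel["subgroup"] = subgroup[:n_tumor]
    gene_panel = pd.DataFrame(panel)

    ihc_vals = np.empty(n_tumor)
    for i, cls in enumerate(subgroup[:n_tumor]):
        comps = config.ihc_dists[cls]
        weights = np.array([c[0] for c in comps], dtype=float)
        k = rng_ihc.choice(len(comps), p=weights / weights.sum())
        ihc_vals[i] = rng_ihc.uniform(comps[k][1], comps[k][2])
    ihc = pd.DataFrame(
        {"sample_id": tumor_ids, "percent_labeled": ihc_vals,
         "control_ok": np.ones(n_tumor, dtype=bool)}
    )

    return SyntheticCohort(
        config=config, sample_sheet=sample_sheet, beta=beta,
        annotation=annotation, meth=meth, unmeth=unmeth,
        gene_panel=gene_panel, ihc=ihc,
    )


def _write_matrix(frame: pd.DataFrame, path: Path) -> None:
    out = frame.copy()
    out.insert(0, "probe_id", frame.index)
    out.to_csv(path, sep="\t", index=False)


def _read_matrix(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("probe_id").rename_axis(None)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the delimited files every downstream stage reads.

    Layout: beta_matrix.tsv, intensities_meth.tsv, intensities_unmeth.tsv
    (probe_id first column, one column per sample), probe_annotation.tsv,
    sample_sheet.csv, gene_panel.csv, ihc.csv. Values round-trip exactly
    through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta_matrix": directory / "beta_matrix.tsv",
        "annotation": directory / "probe_annotation.tsv",
        "meth": directory / "intensities_meth.tsv",
        "unmeth": directory / "intensities_unmeth.tsv",
        "sample_sheet": directory / "sample_sheet.csv",
        "gene_panel": directory / "gene_panel.csv",
        "ihc": directory / "ihc.csv",
    }
    _write_matrix(cohort.beta, paths["beta_matrix"])
    _write_matrix(cohort.meth, paths["meth"])
    _write_matrix(cohort.unmeth, paths["unmeth"])
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    cohort.sample_sheet.to_csv(paths["sample_sheet"], index=False)
    cohort.gene_panel.to_csv(paths["gene_panel"], index=False)
    cohort.ihc.to_csv(paths["ihc"], index=False)
    return paths


def read_cohort(directory, config: CohortConfig | None = None) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    ann = pd.read_csv(directory / "probe_annotation.tsv", sep="\t")
    sheet = pd.read_csv(directory / "sample_sheet.csv")
    if sheet.empty:
        sheet = pd.DataFrame(columns=["sample_id", "subgroup", "age", "has_1q_gain"])
        sheet = sheet.astype({"age": int, "has_1q_gain": bool})
    panel = pd.read_csv(directory / "gene_panel.csv")
    if panel.empty:
        panel = pd.DataFrame(columns=["sample_id"] + list(GENES) + ["subgroup"])
    ihc = pd.read_csv(directory / "ihc.csv")
    if ihc.empty:
        ihc = pd.DataFrame(columns=["sample_id", "percent_labeled", "control_ok"])
        ihc = ihc.astype({"percent_labeled": float, "control_ok": bool})
    return SyntheticCohort(
        config=config if config is not None else CohortConfig(),
        sample_sheet=sheet,
        beta=_read_matrix(directory / "beta_matrix.tsv"),
        annotation=ann,
        meth=_read_matrix(directory / "intensities_meth.tsv"),
        unmeth=_read_matrix(directory / "intensities_unmeth.tsv"),
        gene_panel=panel,
        ihc=ihc,
    )


def config_to_dict(config: CohortConfig) -> dict:
    """JSON-serializable echo of a config (tuples become lists)."""
    d = asdict(config)
    d["gene_panel_dists"] = {g: {c: list(p) for c, p in v.items()}
                             for g, v in config.gene_panel_dists.items()}
    d["ihc_dists"] = {c: [list(t) for t in v] for c, v in config.ihc_dists.items()}
    for k in ("pfa_marker_beta", "pfb_marker_beta", "background_beta"):
        d[k] = list(d[k])
    return d
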