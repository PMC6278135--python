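"""Probe filtering and marker discovery on beta-value matrices.

Three rules: drop sex-chromosome probes, keep CpG-island probes whose
across-sample standard deviation exceeds a threshold (the clustering probe
set), and keep probes hypermethylated in PFA (mean beta >= 0.5) while
hypomethylated in PFB (mean beta <= 0.2) — the criteria that reduce the
array to the small subgroup-separating marker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

VALID_CHROMS = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"}
SEX_CHROMS = {"chrX", "chrY"}


@dataclass(frozen=True)
class MarkerSet:
    """An ordered probe subset plus a record of the rule that produced it."""

    probe_ids: tuple[str, ...]
    criterion: str = ""

    def __post_init__(self):
        ids = tuple(self.probe_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate probe ids in marker set")
        object.__setattr__(self, "probe_ids", ids)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __iter__(self):
        return iter(self.probe_ids)

    def __contains__(self, probe_id) -> bool:
        return probe_id in set(self.probe_ids)


def _check_annotation(annotation: pd.DataFrame) -> None:
    if annotation.empty:
        raise ValidationError("empty probe annotation")
    unknown = set(annotation["chrom"]) - VALID_CHROMS
    if unknown:
        raise ValidationError(f"unknown chromosome labels: {sorted(unknown)}")


def validate_beta_matrix(matrix: pd.DataFrame) -> None:
    """No duplicate ids; every non-missing value in [0, 1]."""
    if matrix.index.duplicated().any():
        raise ValidationError("duplicate probe ids in beta matrix")
    if matrix.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in beta matrix")
    vals = matrix.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("beta values outside [0, 1]")


def filter_autosomal(annotation: pd.DataFrame) -> MarkerSet:
    """Probes not on chrX/chrY, in annotation order."""
    _check_annotation(annotation)
    keep = annotation.loc[~annotation["chrom"].isin(SEX_CHROMS), "probe_id"]
    return MarkerSet(probe_ids=tuple(keep),
                     criterion="autosomal (chrom not in {chrX, chrY})")


def select_high_sd_island_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    sd_threshold: float = 0.25,
) -> MarkerSet:
    """CpG-island probes with across-sample SD strictly above the threshold.

    SD uses the unbiased n-1 estimator over non-missing values; probes with
    fewer than two observations are dropped (logged, not an error). The SD is
    computed over exactly the samples present in ``matrix`` — subsetting to a
    tumor group is the caller's job.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 samples to compute an SD")
    if sd_threshold < 0:
        raise ValidationError("sd_threshold must be >= 0")
    _check_annotation(annotation)
    validate_beta_matrix(matrix)
    islands = annotation.loc[annotation["cpg_island"] == 1, "probe_id"]
    islands = [p for p in islands if p in matrix.index]
    sub = matrix.loc[islands]
    n_obs = sub.notna().sum(axis=1)
    too_few = int((n_obs < 2).sum())
    if too_few:
        logger.info("select_high_sd_island_probes: dropped %d probes with <2 observations",
                    too_few)
    sd = sub.std(axis=1, ddof=1)
    keep = sub.index[(n_obs >= 2) & (sd > sd_threshold)]
    return MarkerSet(probe_ids=tuple(keep),
                     criterion=f"cpg_island & SD > {sd_threshold} (ddof=1)")


def select_subgroup_markers(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    hyper_mean_min: float = 0.5,
    hypo_mean_max: float = 0.2,
) -> MarkerSet:
    """Probes hypermethylated in PFA and hypomethylated in PFB.

    Inclusive at both boundaries: mean over PFA samples >= ``hyper_mean_min``
    and mean over PFB samples <= ``hypo_mean_max``.
    """
    validate_beta_matrix(matrix)
    pfa = [s for s in matrix.columns if labels.get(s) == "PFA"]
    pfb = [s for s in matrix.columns if labels.get(s) == "PFB"]
    for cls, samples in (("PFA", pfa), ("PFB", pfb)):
        if not samples:
            raise ValidationError(f"class {cls} has no samples in the matrix")
    pfa_mean = matrix[pfa].mean(axis=1)
    pfb_mean = matrix[pfb].mean(axis=1)
    keep = matrix.index[(pfa_mean >= hyper_mean_min) & (pfb_mean <= hypo_mean_max)]
    return MarkerSet(
        probe_ids=tuple(keep),
        criterion=f"mean(PFA) >= {hyper_mean_min} and mean(PFB) <= {hypo_mean_max}",
    )
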