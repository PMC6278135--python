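"""Copy-number profiles from methylation-array intensities.

The total (methylated + unmethylated) signal of a probe tracks local DNA
copy number. Normal-reference controls define both the probe QC — probes
whose median summed signal falls outside the 5th–95th percentile band across
probes, or whose across-control MAD exceeds the 80th percentile, are
excluded — and the per-probe reference level. A sample's profile is the
log2 ratio of its summed signal to the control median at each retained
probe, re-centered so the sample's median log2 ratio is zero (which absorbs
global intensity scaling). Arm-level calls use the median log2 ratio over an
arm's probes; a chromosome-instability flag counts gain/neutral/loss state
transitions along the chromosome after median smoothing, a proxy for the
oscillating profiles of chromothripsis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .probes import MarkerSet

#: added to every summed intensity before a ratio, to keep log2 finite
INTENSITY_OFFSET = 1.0


@dataclass(frozen=True)
class IntensityMatrix:
    """Paired methylated/unmethylated signal frames (probes x samples)."""

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self):
        if not self.meth.index.equals(self.unmeth.index) or \
           not self.meth.columns.equals(self.unmeth.columns):
            raise ValidationError("meth and unmeth channels have different probe/sample sets")
        for name, frame in (("meth", self.meth), ("unmeth", self.unmeth)):
            if (frame.to_numpy(dtype=float) < 0).any():
                raise ValidationError(f"negative {name} signals")

    @property
    def summed(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    @property
    def sample_ids(self):
        return list(self.meth.columns)


@dataclass(frozen=True)
class ArmCall:
    arm: str
    median_log2: float
    n_probes: int
    call: str  # gain | neutral | loss | insufficient_probes


@dataclass
class CopyNumberProfile:
    """Per-probe centered log2 ratios for one sample, with probe placement."""

    sample_id: str
    log2_ratio: pd.Series  # indexed by probe id
    annotation: pd.DataFrame  # probe_id, chrom, pos, arm for retained probes


def probe_qc(
    controls: IntensityMatrix,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    mad_q: float = 0.8,
) -> MarkerSet:
    """Control-based probe QC.

    Per probe, over controls: the median summed signal and its MAD. Retained
    probes have a median inside the [lower_q, upper_q] quantile band (over
    probes, linear-interpolation quantiles, inclusive bounds) and a MAD at or
    below the mad_q quantile (over probes).
    """
    if len(controls.sample_ids) < 2:
        raise ValidationError("probe_qc needs >= 2 control samples")
    summed = controls.summed
    med = summed.median(axis=1)
    mad = summed.sub(med, axis=0).abs().median(axis=1)
    qlo, qhi = med.quantile(lower_q), med.quantile(upper_q)
    mad_cut = mad.quantile(mad_q)
    keep = med.index[(med >= qlo) & (med <= qhi) & (mad <= mad_cut)]
    return MarkerSet(
        probe_ids=tuple(keep),
        criterion=(f"median summed signal in [Q{lower_q}, Q{upper_q}] "
                   f"and MAD <= Q{mad_q} over {len(controls.sample_ids)} controls"),
    )


def log2_profile(
    sample_id: str,
    samples: IntensityMatrix,
    controls: IntensityMatrix,
    qc: MarkerSet,
    annotation: pd.DataFrame,
    offset: float = INTENSITY_OFFSET,
) -> CopyNumberProfile:
    """Centered per-probe log2 ratio of one sample against the control median."""
    if len(qc) == 0:
        raise ValidationError("empty QC probe set")
    if sample_id not in samples.meth.columns:
        raise ValidationError(f"sample {sample_id!r} not in the intensity matrix")
    probes = [p for p in qc if p in samples.meth.index and p in controls.meth.index]
    sample_sum = samples.summed.loc[probes, sample_id]
    ctrl_med = controls.summed.loc[probes].median(axis=1)
    denom = ctrl_med + offset
    bad = denom.index[denom <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive control medians after offset for probes: {list(bad)[:10]}")
    ratio = np.log2((sample_sum + offset) / denom)
    ratio = ratio - ratio.median()
    ann = annotation.set_index("probe_id").loc[probes, ["chrom", "pos", "arm"]].reset_index()
    return CopyNumberProfile(sample_id=sample_id, log2_ratio=ratio, annotation=ann)


def call_arm(
    profile: CopyNumberProfile,
    arm: str,
    gain_threshold: float = 0.15,
    loss_threshold: float = -0.15,
    min_probes: int = 20,
) -> ArmCall:
    """Gain/neutral/loss from the arm's median log2 ratio."""
    probes = profile.annotation.loc[profile.annotation["arm"] == arm, "probe_id"]
    if probes.empty:
        raise ValidationError(f"arm {arm!r} not present in the profile annotation")
    vals = profile.log2_ratio.loc[probes]
    med = float(vals.median())
    n = int(len(vals))
    if n < min_probes:
        return ArmCall(arm=arm, median_log2=med, n_probes=n, call="insufficient_probes")
    if med >= gain_threshold:
        call = "gain"
    elif med <= loss_threshold:
        call = "loss"
    else:
        call = "neutral"
    return ArmCall(arm=arm, median_log2=med, n_probes=n, call=call)


def call_all_arms(profile: CopyNumberProfile, **kwargs) -> list[ArmCall]:
    arms = profile.annotation["arm"].drop_duplicates()
    return [call_arm(profile, arm, **kwargs) for arm in arms]


def instability_flag(
    profile: CopyNumberProfile,
    chrom: str,
    amp_threshold: float = 0.3,
    min_transitions: int = 10,
    smooth_window: int = 5,
) -> tuple[bool, int]:
    """Oscillation proxy for chromothripsis on one chromosome.

    Probes are ordered by position, median-smoothed (centered window), each
    discretized to {-1, 0, +1} via +/- ``amp_threshold``, and the number of
    state changes along the chromosome is counted; the flag is raised at
    ``min_transitions`` or more.
    """
    ann = profile.annotation[profile.annotation["chrom"] == chrom]
    if ann.empty:
        raise ValidationError(f"chromosome {chrom!r} not present in the profile")
    ordered = ann.sort_values(["arm", "pos"], kind="stable")["probe_id"]
    vals = profile.log2_ratio.loc[ordered]
    smooth = vals.rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
    states = np.where(smooth >= amp_threshold, 1, np.where(smooth <= -amp_threshold, -1, 0))
    transitions = int((np.diff(states) != 0).sum())
    return transitions >= min_transitions, transitions
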