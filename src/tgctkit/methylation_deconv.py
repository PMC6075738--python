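"""Two-component methylation deconvolution and downstream methylome calls.

Seminomas are heavily infiltrated by lymphocytes, and the bulk methylome is
a two-component mixture: observed beta = f * lymphocyte_ref + (1 - f) *
tumor_beta, where f is the lymphocyte fraction. This module estimates f
from lymphocyte-specific signature probes (a LUMP-style ratio of means),
inverts the mixture to recover tumor-intrinsic beta values, and builds on
the corrected values: density/modality summaries, the recurrent residual
methylation fraction in seminomas, CpH (non-CpG) methylation scores that
track embryonal carcinoma content, imprinted-DMR states, and promoter
epigenetic-silencing calls.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .exceptions import EstimationError, ValidationError
from .types import BetaMatrix, DensitySummary, LymphocyteEstimate, SilencingCall

logger = logging.getLogger(__name__)

MIN_SIGNATURE_PROBES = 20
MIN_CPH_PROBES = 50
MIN_DENSITY_VALUES = 500
#: Corrected beta at/above which a probe counts as methylated.
METHYLATED_BETA = 0.3
#: Fraction of samples at which probe methylation counts as recurrent.
RECURRENCE_FRACTION = 0.1
#: Imprinted-DMR state bands on mean corrected beta.
IMPRINT_ERASED_MAX = 0.15
IMPRINT_BIPARENTAL_RANGE = (0.35, 0.65)
DENSITY_BANDWIDTH = 0.03


def estimate_lymphocyte_fraction(beta: BetaMatrix, annotation: pd.DataFrame,
                                 min_probes: int = MIN_SIGNATURE_PROBES,
                                 ) -> list[LymphocyteEstimate]:
    """Estimate per-sample lymphocyte fraction from signature probes.

    f = clip(mean(observed beta at signature probes) /
             mean(lymphocyte reference beta at those probes), 0, 1).
    Probes missing in a sample are skipped; fewer than ``min_probes`` usable
    probes raises :class:`EstimationError`.
    """
    sig = annotation.index[annotation["lymphocyte_signature"].astype(bool)]
    sig = [p for p in sig if p in beta.beta.index]
    if len(sig) < min_probes:
        raise EstimationError(
            f"{len(sig)} signature probes available, need >= {min_probes}")
    obs = beta.beta.loc[sig]
    ref = annotation.loc[sig, "lymphocyte_ref_beta"].astype(float).to_numpy()
    estimates = []
    for sample in beta.sample_ids:
        vals = obs[sample].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        n = int(mask.sum())
        if n < min_probes:
            raise EstimationError(
                f"sample {sample}: {n} usable signature probes, "
                f"need >= {min_probes}")
        f = float(np.clip(vals[mask].mean() / ref[mask].mean(), 0.0, 1.0))
        estimates.append(LymphocyteEstimate(sample_id=sample, f=f, n_probes_used=n))
    return estimates


def mixture_fractions(estimates: Iterable[LymphocyteEstimate]) -> dict[str, float]:
    """Convenience mapping sample_id -> estimated lymphocyte fraction."""
    return {e.sample_id: e.f for e in estimates}


def correct_beta(beta_obs: float, f: float, ref_beta: float) -> float:
    """Remove the lymphocyte contribution from one observed beta value.

    corrected = clip((beta_obs - f * ref_beta) / (1 - f), 0, 1); exact
    inverse of the two-component mixture before clipping. f = 1 leaves no
    tumor signal and is a domain error.
    """
    for name, v in (("beta_obs", beta_obs), ("f", f), ("ref_beta", ref_beta)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    if f == 1.0:
        raise ValueError("f = 1: no tumor signal to recover")
    return float(np.clip((beta_obs - f * ref_beta) / (1.0 - f), 0.0, 1.0))


def correct_beta_matrix(beta: BetaMatrix, fractions: Mapping[str, float],
                        annotation: pd.DataFrame) -> BetaMatrix:
    """Lymphocyte-correct a whole beta matrix.

    Uses the per-probe ``lymphocyte_ref_beta`` column (which the annotation
    must populate for every probe; CpH probes carry reference 0 because
    lymphocytes lack CpH methylation). Negative pre-clip mass is a
    diagnostic of f overestimation and is logged.
    """
    ref = annotation.loc[beta.beta.index, "lymphocyte_ref_beta"].astype(float)
    if ref.isna().any():
        raise ValidationError("lymphocyte_ref_beta missing for some probes; "
                              "correction needs a reference for every probe")
    ref_v = ref.to_numpy()[:, None]
    f = np.array([fractions[s] for s in beta.sample_ids])[None, :]
    if np.any(f >= 1.0):
        raise ValueError("f = 1 for at least one sample: no tumor signal")
    raw = (beta.beta.to_numpy() - f * ref_v) / (1.0 - f)
    neg = np.nanmean(raw < -1e-9)
    if neg > 0:
        logger.info("correct_beta_matrix: %.2f%% of entries clipped at 0 "
                    "(possible f overestimation)", 100 * neg)
    corrected = pd.DataFrame(np.clip(raw, 0.0, 1.0), index=beta.beta.index,
                             columns=beta.sample_ids)
    return BetaMatrix(corrected)


def density_summary(values, label: str = "",
                    bandwidth: float = DENSITY_BANDWIDTH,
                    prominence_fraction: float = 0.05,
                    grid_size: int = 2048,
                    min_values: int = MIN_DENSITY_VALUES) -> DensitySummary:
    """Summarise the modality of a beta-value distribution.

    Gaussian kernel density on [0, 1] with boundary reflection; modes are
    local maxima with prominence >= ``prominence_fraction`` of the maximum
    density (boundary peaks at 0 and 1 are eligible via the reflection).
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size < min_values:
        raise EstimationError(
            f"{vals.size} values, need >= {min_values} for a density summary")
    edges = np.linspace(0.0, 1.0, grid_size + 1)
    width = edges[1] - edges[0]
    hist, _ = np.histogram(vals, bins=edges)
    # 'mirror' reflection implements the boundary-reflected KDE on [0, 1]
    dens = gaussian_filter1d(hist.astype(float), sigma=bandwidth / width,
                             mode="mirror")
    dens /= vals.size * width
    # extend by mirrored flanks so boundary modes register as local maxima
    k = min(grid_size - 1, max(2, int(np.ceil(4 * bandwidth / width))))
    ext = np.concatenate([dens[k:0:-1], dens, dens[-2:-k - 2:-1]])
    idx, _ = find_peaks(ext, prominence=prominence_fraction * dens.max())
    centers = (edges[:-1] + edges[1:]) / 2
    peaks = sorted(
        float(centers[i - k]) for i in idx if k <= i < k + grid_size
    )
    return DensitySummary(
        label=label,
        peak_positions=tuple(peaks),
        n_modes=len(peaks),
        mass_above_03=float(np.mean(vals > METHYLATED_BETA)),
    )


def residual_methylation_fraction(corrected: BetaMatrix,
                                  beta_threshold: float = METHYLATED_BETA,
                                  recurrence: float = RECURRENCE_FRACTION,
                                  ) -> float:
    """Fraction of probes recurrently methylated after correction.

    A probe counts when its corrected beta is >= ``beta_threshold`` in at
    least ``recurrence`` of the samples. Needs >= 2 samples.
    """
    if corrected.beta.shape[1] < 2:
        raise ValidationError("recurrence needs >= 2 samples")
    methylated = (corrected.beta >= beta_threshold)
    recurrent = methylated.mean(axis=1) >= recurrence
    return float(recurrent.mean())


def cph_score(beta: BetaMatrix, annotation: pd.DataFrame,
              fractions: Mapping[str, float],
              min_probes: int = MIN_CPH_PROBES) -> pd.Series:
    """Per-sample mean CpH (non-CpG) methylation after lymphocyte correction.

    Lymphocytes carry no CpH methylation (reference 0), so the correction
    reduces to dividing by the tumor fraction. CpH methylation is an
    embryonic-stem-cell hallmark and scales with embryonal carcinoma
    content.
    """
    cph = annotation.index[annotation["context"] == "CpH"]
    cph = [p for p in cph if p in beta.beta.index]
    if len(cph) < min_probes:
        raise EstimationError(
            f"{len(cph)} CpH probes available, need >= {min_probes}")
    obs = beta.beta.loc[cph]
    scores = {}
    for sample in beta.sample_ids:
        f = fractions[sample]
        if f >= 1.0:
            raise ValueError(f"sample {sample}: f = 1, no tumor signal")
        corrected = np.clip(obs[sample].to_numpy(dtype=float) / (1.0 - f), 0, 1)
        scores[sample] = float(np.nanmean(corrected))
    return pd.Series(scores, name="cph_score")


def imprinting_survey(beta: BetaMatrix, annotation: pd.DataFrame,
                      fractions: Mapping[str, float]) -> pd.DataFrame:
    """Classify imprinted-DMR methylation per (sample, DMR).

    States on the mean corrected beta per DMR: ``erased`` (< 0.15, the
    germline-like erasure typical of TGCT), ``biparental`` ([0.35, 0.65],
    the somatic parent-of-origin pattern), ``methylated`` (> 0.65). Values
    between bands are assigned the nearest state with ``boundary`` flagged.
    """
    dmr_probes = annotation[annotation["imprinted_dmr"].notna()]
    if dmr_probes.empty:
        raise ValidationError("no imprinted DMRs annotated")
    corrected = correct_beta_matrix(
        beta.subset(probes=dmr_probes.index), fractions, annotation)
    lo, hi = IMPRINT_BIPARENTAL_RANGE
    rows = []
    for dmr, probes in dmr_probes.groupby("imprinted_dmr").groups.items():
        probes = [p for p in probes if p in corrected.beta.index]
        means = corrected.beta.loc[probes].mean(axis=0)
        for sample, value in means.items():
            boundary = False
            if value < IMPRINT_ERASED_MAX:
                state = "erased"
            elif lo <= value <= hi:
                state = "biparental"
            elif value > hi:
                state = "methylated"
            else:  # gap between erased and biparental bands
                state = ("erased" if value - IMPRINT_ERASED_MAX < lo - value
                         else "biparental")
                boundary = True
            rows.append((sample, dmr, float(value), state, boundary))
    return pd.DataFrame(rows, columns=[
        "sample_id", "dmr", "mean_corrected_beta", "state", "boundary"])


def call_epigenetic_silencing(corrected: BetaMatrix, annotation: pd.DataFrame,
                              expression: pd.DataFrame,
                              genes: Optional[Sequence[str]] = None,
                              beta_threshold: float = METHYLATED_BETA,
                              ref_beta_max: float = 0.1,
                              expression_quantile: float = 0.25,
                              ) -> list[SilencingCall]:
    """Call promoter epigenetic silencing per (sample, gene).

    A gene is silenced in a sample when its mean corrected promoter beta is
    >= ``beta_threshold`` and its expression is at or below the
    ``expression_quantile`` of samples whose promoter is unmethylated
    (corrected beta < ``ref_beta_max``). Genes without unmethylated
    reference samples yield indeterminate calls (``silenced=None``).
    """
    promoter = annotation[annotation["promoter_of_gene"].notna()]
    if genes is None:
        genes = sorted(promoter["promoter_of_gene"].unique())
    calls = []
    for gene in genes:
        probes = promoter.index[promoter["promoter_of_gene"] == gene]
        probes = [p for p in probes if p in corrected.beta.index]
        if not probes or gene not in expression.index:
            warnings.warn(f"gene {gene!r}: no promoter probes or expression; "
                          "skipped", stacklevel=2)
            continue
        prom_beta = corrected.beta.loc[probes].mean(axis=0)
        expr = expression.loc[gene]
        ref_samples = prom_beta.index[(prom_beta < ref_beta_max)
                                      & prom_beta.index.isin(expr.index)]
        threshold = (float(expr[ref_samples].quantile(expression_quantile))
                     if len(ref_samples) else None)
        for sample in corrected.sample_ids:
            if sample not in expr.index:
                continue
            b, e = float(prom_beta[sample]), float(expr[sample])
            silenced: Optional[bool]
            if threshold is None:
                silenced = None
            else:
                silenced = bool(b >= beta_threshold and e <= threshold)
            calls.append(SilencingCall(
                sample_id=sample, gene=gene, promoter_beta_corrected=b,
                expression_log2=e, silenced=silenced))
    return calls
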