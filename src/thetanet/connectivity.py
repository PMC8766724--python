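"""MVAR model fitting and directed-transfer-function (DTF) connectivity.

The encoding-phase EEG is modeled as a multivariate autoregressive (MVAR)
process

    x(t) = A_1 x(t-1) + ... + A_p x(t-p) + e(t),

fitted by multi-epoch ordinary least squares (regressors never span epoch
boundaries). From the fitted coefficients the spectral transfer matrix

    H(f) = [I − Σ_r A_r exp(−i 2π f r / fs)]⁻¹

is formed, and the DTF from channel j to channel i at frequency f is the
row-normalized squared transfer gain

    γ_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²,

so every row of γ sums to one: γ_ij is the fraction of the total inflow
into sink i attributable to source j. Band-averaged γ is aggregated three
ways: a global off-diagonal mean (DTF_g), a per-channel in+out strength
(DTF_i), and region-pair means (DTF_kl) from which frontal outflow/inflow
(DTF_out / DTF_in) are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import RegionMap, normalize_label
from .preprocess import EpochSet

__all__ = [
    "MVARModel",
    "DTFResult",
    "fit_mvar",
    "companion_spectral_radius",
    "transfer_matrix",
    "dtf",
    "band_average_dtf",
    "global_dtf",
    "node_dtf",
    "region_dtf",
    "region_pair_matrix",
    "hub_flows",
    "dtf_analysis",
]

logger = logging.getLogger(__name__)


class UnstableModelError(ValueError):
    """Raised when MVAR coefficients describe a non-stationary process."""


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the (k·p) x (k·p) companion matrix of A_1..A_p."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    comp = np.zeros((k * p, k * p))
    comp[:k] = coeffs.transpose(1, 0, 2).reshape(k, k * p)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass(frozen=True)
class MVARModel:
    """A fitted (or constructed) MVAR model.

    ``coeffs`` has shape (order, k, k): coeffs[r-1][i, j] is the influence
    of channel j at lag r on channel i.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", coeffs)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (order, k, k)")
        if coeffs.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel required")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


def _solve_normal(
    gram: np.ndarray, xty: np.ndarray, n_eff: int
) -> tuple[np.ndarray, int]:
    """Minimum-norm least squares from the normal equations.

    Uses an eigendecomposition of the Gram matrix (cheap: parameters are
    few, samples many) with an lstsq-style relative cutoff, so exact
    collinearity is handled identically to ``np.linalg.lstsq``.
    """
    evals, evecs = np.linalg.eigh(gram)
    cutoff = np.finfo(float).eps * max(n_eff, gram.shape[0]) * max(evals.max(), 0.0)
    keep = evals > cutoff
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / evals[keep]
    beta = (evecs * inv) @ (evecs.T @ xty)
    return beta, int(keep.sum())


def fit_mvar(
    epochs: EpochSet | np.ndarray,
    order: int | str = "auto",
    criterion: str = "bic",
    max_order: int = 20,
    fs: float | None = None,
    channel_labels: tuple[str, ...] | None = None,
) -> MVARModel:
    """Fit an MVAR model to (multi-epoch) data by least squares.

    ``order="auto"`` selects the lag count in [1, max_order] minimizing AIC
    or BIC of the multivariate residual covariance; the choice is logged.
    A 2-D array is treated as a single epoch.
    """
    if isinstance(epochs, EpochSet):
        data, fs, channel_labels = epochs.data, epochs.fs, epochs.channel_labels
    else:
        data = np.asarray(epochs, dtype=float)
        if data.ndim == 2:
            data = data[np.newaxis]
        if fs is None or channel_labels is None:
            raise ValueError("fs and channel_labels required for array input")
    n_trials, k, n = data.shape
    total = n_trials * n

    if order == "auto":
        crit = criterion.lower()
        if crit not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        best = None
        for p in range(1, max_order + 1):
            if total - n_trials * p <= k * p + k:
                break
            model, sigma, n_eff = _fit_fixed(data, p, fs, channel_labels)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                logdet = -np.inf  # degenerate fit; treat as overfit
            n_params = k * k * p
            penalty = (
                2.0 * n_params / n_eff
                if crit == "aic"
                else n_params * np.log(n_eff) / n_eff
            )
            score = logdet + penalty
            if best is None or score < best[0]:
                best = (score, p, model)
        if best is None:
            raise ValueError("not enough data to fit any order")
        logger.info("auto order selection (%s): order=%d", crit, best[1])
        return best[2]

    model, _, _ = _fit_fixed(data, int(order), fs, channel_labels)
    return model


def _normal_equations(data: np.ndarray, order: int):
    """Gram matrix, cross-products and Y'Y without materializing the
    design matrix: batched matmuls over epochs."""
    n_trials, k, n = data.shape
    lagged = np.concatenate(
        [data[:, :, order - r : n - r] for r in range(1, order + 1)], axis=1
    )  # (trials, k*p, n-p)
    y = data[:, :, order:]
    gram = np.einsum("tin,tjn->ij", lagged, lagged, optimize=True)
    xty = np.einsum("tin,tjn->ij", lagged, y, optimize=True)
    yty = np.einsum("tin,tjn->ij", y, y, optimize=True)
    n_eff = n_trials * (n - order)
    return gram, xty, yty, n_eff


def _fit_fixed(data, order, fs, channel_labels):
    n_trials, k, n = data.shape
    if n <= order:
        raise ValueError(f"epochs of {n} samples cannot support order {order}")
    gram, xty, yty, n_eff = _normal_equations(data, order)
    n_params = k * order
    if n_eff < n_params:
        raise ValueError(
            f"only {n_eff} regression rows for {n_params} parameters; "
            "use fewer channels, a lower order, or more data"
        )
    beta, rank = _solve_normal(gram, xty, n_eff)
    if rank < n_params:
        # Exact collinearity of at most one direction per lag is expected
        # after common average referencing (channels sum to zero); the
        # minimum-norm solution is the standard resolution. Anything worse
        # points at genuinely insufficient or degenerate data.
        if rank < n_params - order:
            raise ValueError(
                f"rank-deficient MVAR regression (rank {rank} < "
                f"{n_params} parameters); use fewer channels or more data"
            )
        logger.info(
            "MVAR regression rank %d < %d (common-average-referenced data); "
            "using the minimum-norm least-squares solution",
            rank,
            n_params,
        )
    # residual covariance in closed form: (Y − Xβ)'(Y − Xβ)
    rss = yty - beta.T @ xty - xty.T @ beta + beta.T @ gram @ beta
    rss = (rss + rss.T) / 2.0
    dof = max(n_eff - n_params, 1)
    sigma = rss / dof
    coeffs = beta.T.reshape(k, order, k).transpose(1, 0, 2)
    model = MVARModel(
        coeffs=coeffs,
        noise_cov=sigma,
        fs=float(fs),
        channel_labels=tuple(channel_labels),
    )
    if not model.is_stable:
        logger.warning(
            "fitted MVAR is unstable (spectral radius %.4f)", model.spectral_radius
        )
    return model, sigma, n_eff


# --------------------------------------------------------------------------
# Spectral transfer matrix and DTF
# --------------------------------------------------------------------------

def transfer_matrix(model: MVARModel, freq_grid: np.ndarray) -> np.ndarray:
    """H(f) = [I − Σ_r A_r e^{−i 2π f r / fs}]⁻¹ for each grid frequency.

    Returns a complex array of shape (n_freqs, k, k).
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid >= model.fs / 2):
        raise ValueError("frequencies must lie below Nyquist")
    if not model.is_stable:
        raise UnstableModelError(
            f"model spectral radius {model.spectral_radius:.4f} >= 1"
        )
    p, k, _ = model.coeffs.shape
    lags = np.arange(1, p + 1)
    # phase[f, r] = exp(-i 2 pi f r / fs)
    phase = np.exp(-2j * np.pi * np.outer(freq_grid, lags) / model.fs)
    a_f = np.eye(k) - np.einsum("fr,rij->fij", phase, model.coeffs)
    out = np.empty_like(a_f)
    for idx in range(len(freq_grid)):
        try:
            out[idx] = np.linalg.inv(a_f[idx])
        except np.linalg.LinAlgError:
            raise ValueError(
                f"A(f) singular at f={freq_grid[idx]:g} Hz"
            ) from None
    return out


def dtf(model: MVARModel, freq_grid: np.ndarray) -> np.ndarray:
    """Frequency-resolved DTF γ[f, sink i, source j]; rows sum to 1."""
    h = transfer_matrix(model, freq_grid)
    power = np.abs(h) ** 2
    denom = power.sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("zero total transfer gain in some row of H(f)")
    return power / denom


def band_average_dtf(
    gamma: np.ndarray, freq_grid: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Mean of γ over grid frequencies with low <= f < high."""
    low, high = band
    mask = (np.asarray(freq_grid) >= low) & (np.asarray(freq_grid) < high)
    if not mask.any():
        raise ValueError(f"band [{low}, {high}) contains no grid frequencies")
    return gamma[mask].mean(axis=0)


def global_dtf(band_gamma: np.ndarray) -> float:
    """Mean of the off-diagonal entries of the band-averaged DTF matrix."""
    band_gamma = np.asarray(band_gamma)
    n = band_gamma.shape[0]
    if band_gamma.ndim != 2 or band_gamma.shape[1] != n or n < 2:
        raise ValueError("band_gamma must be square with k >= 2")
    off = band_gamma.sum() - np.trace(band_gamma)
    return float(off / (n * (n - 1)))


def node_dtf(
    band_gamma: np.ndarray,
    channel: str | int,
    channel_labels: tuple[str, ...] | None = None,
) -> float:
    """In+out strength of one channel: (1/(2(n−1))) Σ_{j≠i}(γ_ji + γ_ij)."""
    band_gamma = np.asarray(band_gamma)
    n = band_gamma.shape[0]
    if isinstance(channel, str):
        if channel_labels is None:
            raise ValueError("channel_labels required for label lookup")
        try:
            i = list(channel_labels).index(normalize_label(channel))
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
    else:
        i = int(channel)
    inflow = band_gamma[i].sum() - band_gamma[i, i]
    outflow = band_gamma[:, i].sum() - band_gamma[i, i]
    return float((inflow + outflow) / (2 * (n - 1)))


def region_dtf(
    band_gamma: np.ndarray,
    regions: RegionMap,
    source: str,
    sink: str,
    channel_labels: tuple[str, ...],
) -> float:
    """Mean DTF over sink-region rows and source-region columns.

    For source == sink, diagonal (self) entries are excluded: γ_ii is a
    normalization remainder, not a connection.
    """
    regions = regions.restricted(channel_labels)
    labels = list(channel_labels)
    rows = [labels.index(c) for c in regions.channels_in(sink) if c in labels]
    cols = [labels.index(c) for c in regions.channels_in(source) if c in labels]
    if not rows or not cols:
        raise ValueError(f"region pair ({sink!r} <- {source!r}) has no channels")
    sub = np.asarray(band_gamma)[np.ix_(rows, cols)]
    if source == sink:
        mask = ~np.eye(len(rows), dtype=bool)
        if not mask.any():
            raise ValueError(f"region {source!r} has a single channel; "
                             "within-region DTF undefined")
        return float(sub[mask].mean())
    return float(sub.mean())


def region_pair_matrix(
    band_gamma: np.ndarray, regions: RegionMap, channel_labels: tuple[str, ...]
) -> pd.DataFrame:
    """Full region x region DTF matrix (rows = sink, columns = source)."""
    names = regions.regions
    out = pd.DataFrame(index=list(names), columns=list(names), dtype=float)
    for sink in names:
        for source in names:
            if sink == source and len(regions.channels_in(sink)) < 2:
                out.loc[sink, source] = np.nan  # within-region DTF undefined
                continue
            out.loc[sink, source] = region_dtf(
                band_gamma, regions, source, sink, channel_labels
            )
    return out


def hub_flows(
    band_gamma: np.ndarray,
    regions: RegionMap,
    hub: str,
    channel_labels: tuple[str, ...],
) -> tuple[float, float]:
    """(DTF_out, DTF_in) for a hub region.

    DTF_out is the mean over non-hub sink regions of region_dtf(source=hub);
    DTF_in is the mean over non-hub source regions of region_dtf(sink=hub).
    """
    others = [r for r in regions.regions if r != hub]
    if not others:
        raise ValueError("hub_flows needs at least two regions")
    out = np.mean(
        [region_dtf(band_gamma, regions, hub, k, channel_labels) for k in others]
    )
    inn = np.mean(
        [region_dtf(band_gamma, regions, l, hub, channel_labels) for l in others]
    )
    return float(out), float(inn)


@dataclass(frozen=True)
class DTFResult:
    """Connectivity summary for one subject and one frequency band."""

    gamma: np.ndarray                 # (n_freqs, k, k)
    freq_grid: np.ndarray
    band: tuple[float, float]
    band_gamma: np.ndarray            # (k, k)
    channel_labels: tuple[str, ...]
    dtf_g: float
    dtf_i: pd.Series                  # per channel
    dtf_kl: pd.DataFrame              # region x region (sink x source)
    region_strength: pd.Series        # region mean of dtf_i
    dtf_out: float
    dtf_in: float
    hub_region: str
    mvar_order: int


def dtf_analysis(
    model: MVARModel,
    regions: RegionMap,
    band: tuple[float, float] = (4.0, 8.0),
    hub_region: str = "F",
    freq_resolution: float = 0.5,
) -> DTFResult:
    """Full DTF analysis of a fitted model: γ(f) plus all aggregates."""
    freq_grid = np.arange(freq_resolution, model.fs / 2, freq_resolution)
    gamma = dtf(model, freq_grid)
    band_gamma = band_average_dtf(gamma, freq_grid, band)
    labels = model.channel_labels
    dtf_i = pd.Series(
        {c: node_dtf(band_gamma, i) for i, c in enumerate(labels)}, dtype=float
    )
    regions_r = regions.restricted(labels)
    from .spectral import region_power  # local import avoids a cycle

    region_strength = region_power(dtf_i, regions_r)
    dtf_kl = region_pair_matrix(band_gamma, regions_r, labels)
    out, inn = hub_flows(band_gamma, regions_r, hub_region, labels)
    return DTFResult(
        gamma=gamma,
        freq_grid=freq_grid,
        band=band,
        band_gamma=band_gamma,
        channel_labels=labels,
        dtf_g=global_dtf(band_gamma),
        dtf_i=dtf_i,
        dtf_kl=dtf_kl,
        region_strength=region_strength,
        dtf_out=out,
        dtf_in=inn,
        hub_region=hub_region,
        mvar_order=model.order,
    )
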