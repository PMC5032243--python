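"""Temperature reconstruction from subsampled dynamic k-space.

Four routes are provided:

* ``full_recon`` — reference inverse transform of fully sampled data;
* ``sliding_window_recon`` — view sharing: each unsampled k-space location
  takes its most recently acquired value;
* ``mpf_recon`` — model predictive filtering: a bioheat forward prediction of
  the temperature map is converted through the PRFS relation into a predicted
  complex image whose k-space fills the unsampled locations (acquired samples
  are kept bit-exactly — data fidelity is hard);
* ``tcr_recon`` — temporally constrained reconstruction: gradient descent on
  a k-space fidelity term plus a temporal smoothed-L1 penalty.

All temperatures are phase differences against the pre-heating baseline
image, computed by complex-conjugate multiplication (no unwrapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .mracq import KSpaceFrame, PRFSConstants, fft3c, ifft3c, phase_to_temp, temp_to_phase
from .phantoms import MediumGrid
from .thermal import PBTESolver, PowerSchedule, TemperatureSeries, simulate_heating

__all__ = [
    "ReconResult",
    "full_recon",
    "zero_fill",
    "mpf_recon",
    "tcr_recon",
    "sliding_window_recon",
]


@dataclass
class ReconResult:
    """A reconstructed temperature series plus per-frame diagnostics."""

    series: TemperatureSeries
    method: str
    diagnostics: dict = field(default_factory=dict)
    images: np.ndarray | None = None


def _dT_from_image(img: np.ndarray, baseline: np.ndarray,
                   consts: PRFSConstants) -> np.ndarray:
    return np.asarray(phase_to_temp(np.angle(img * np.conj(baseline)), consts))


def full_recon(frame: KSpaceFrame) -> np.ndarray:
    """Centered inverse transform of a fully sampled frame."""
    if not frame.fully_sampled:
        raise ValueError("full_recon requires fully sampled k-space")
    return ifft3c(frame.data)


def zero_fill(volume: np.ndarray, spacing, target_spacing,
              domain: str = "image") -> tuple[np.ndarray, tuple[float, ...]]:
    """Zero-filled (sinc) interpolation to a finer grid via symmetric
    k-space padding; amplitudes are preserved, so temperatures keep their
    scale.  Returns the interpolated volume and the achieved spacing
    (n*d/n_new per axis, the closest DFT-realizable spacing <= target).
    """
    volume = np.asarray(volume)
    spacing = tuple(float(s) for s in spacing)
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * volume.ndim
    target_spacing = tuple(float(s) for s in target_spacing)
    new_shape = []
    for n, d, t in zip(volume.shape, spacing, target_spacing):
        if t > d * (1 + 1e-9):
            raise ValueError(f"target spacing {t} coarser than native {d}")
        new_shape.append(max(n, int(round(n * d / t))))
    new_shape = tuple(new_shape)
    if new_shape == volume.shape:
        out = volume if domain == "image" else ifft3c(volume)
        return out, spacing
    was_real = domain == "image" and not np.iscomplexobj(volume)
    k = fft3c(volume.astype(complex)) if domain == "image" else np.asarray(volume, dtype=complex)
    pad = []
    for n, m in zip(volume.shape, new_shape):
        left = m // 2 - n // 2
        pad.append((left, m - n - left))
    k = np.pad(k, pad)
    scale = np.sqrt(np.prod(new_shape) / np.prod(volume.shape))
    out = ifft3c(k) * scale
    if was_real:
        out = out.real
    new_spacing = tuple(n * d / m for n, d, m in
                        zip(volume.shape, spacing, new_shape))
    return out, new_spacing


# ---------------------------------------------------------------------------
# sliding window
# ---------------------------------------------------------------------------

def sliding_window_recon(frames: list[KSpaceFrame], baseline_image: np.ndarray,
                         consts: PRFSConstants,
                         keep_images: bool = False) -> ReconResult:
    """View sharing: per frame, composite k-space holding the most recent
    acquired value at every location (current frame preferred).  Locations
    never sampled in any frame so far fall back to the baseline's k-space.
    """
    _check_frames(frames)
    latest = fft3c(np.asarray(baseline_image, dtype=complex))
    dTs, times, images = [], [], []
    for fr in frames:
        latest = np.where(fr.mask.pattern[None, :, :], fr.data, latest)
        img = ifft3c(latest)
        dTs.append(_dT_from_image(img, baseline_image, consts))
        times.append(fr.t_center)
        if keep_images:
            images.append(img)
    series = TemperatureSeries(frames=np.stack(dTs), times=np.asarray(times),
                               spacing=(1.0, 1.0, 1.0))
    return ReconResult(series=series, method="sliding_window",
                       diagnostics={"fill_fraction":
                                    [f.mask.sampled_fraction for f in frames]},
                       images=np.stack(images) if keep_images else None)


def _check_frames(frames) -> None:
    if len(frames) == 0:
        raise ValueError("no k-space frames given")
    times = [f.t_center for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("frames must be time-ordered")


# ---------------------------------------------------------------------------
# model predictive filtering
# ---------------------------------------------------------------------------

def mpf_recon(frames: list[KSpaceFrame], medium: MediumGrid, q_field: np.ndarray,
              baseline_image: np.ndarray, consts: PRFSConstants,
              power_schedule: PowerSchedule, t0: float = 0.0,
              q_support_frac: float = 0.0, safety: float = 0.5,
              keep_images: bool = False) -> ReconResult:
    """Model-predictive-filtering reconstruction.

    Per frame n+1: (1) the bioheat model advances the current temperature map
    over the inter-frame interval using the deposition map ``q_field`` scaled
    by the power schedule; (2) the predicted map becomes a phase change which,
    with the previous frame's magnitude, forms a predicted complex image;
    (3) its k-space fills the unsampled locations of the acquired frame
    (acquired samples are kept exactly); (4) the composite is inverse
    transformed and the PRFS phase against the baseline gives the new map.

    ``q_support_frac`` implements the off-focal convention: voxels with
    Q below this fraction of max(Q) get Q = k = W = 0 in the model, so the
    prediction carries the prior frame there and unsampled k-space follows a
    sliding-window behaviour.
    """
    _check_frames(frames)
    q = np.asarray(q_field, dtype=float)
    if q.shape != medium.shape:
        raise ValueError("q_field must live on the model (image) grid")
    if q_support_frac > 0:
        support = q >= q_support_frac * q.max()
        med = dc_replace(medium,
                         k_th=np.where(support, medium.k_th, 0.0),
                         w_perf=np.where(support, medium.w_perf, 0.0))
        q = np.where(support, q, 0.0)
    else:
        med = medium
    solver = PBTESolver(med, bc="dirichlet")
    baseline_image = np.asarray(baseline_image, dtype=complex)
    phase_b = np.angle(baseline_image)
    prev_mag = np.abs(baseline_image)
    dT = np.zeros(medium.shape)
    t_curr = t0
    dTs, times, fill, images = [], [], [], []
    for fr in frames:
        if fr.t_center <= t_curr:
            raise ValueError("frame center times must advance past t0")
        pred = simulate_heating(med, q, power_schedule, [fr.t_center],
                                solver=solver, dT0=dT, t0=t_curr,
                                safety=safety).frames[0]
        pred_img = prev_mag * np.exp(1j * (phase_b + temp_to_phase(pred, consts)))
        k_pred = fft3c(pred_img)
        composite = np.where(fr.mask.pattern[None, :, :], fr.data, k_pred)
        img = ifft3c(composite)
        dT = _dT_from_image(img, baseline_image, consts)
        prev_mag = np.abs(img)
        t_curr = fr.t_center
        dTs.append(dT)
        times.append(fr.t_center)
        fill.append(fr.mask.sampled_fraction)
        if keep_images:
            images.append(img)
    series = TemperatureSeries(frames=np.stack(dTs), times=np.asarray(times),
                               spacing=medium.spacing, origin=medium.origin)
    return ReconResult(series=series, method="mpf",
                       diagnostics={"fill_fraction": fill,
                                    "q_support_frac": q_support_frac},
                       images=np.stack(images) if keep_images else None)


# ---------------------------------------------------------------------------
# temporally constrained reconstruction
# ---------------------------------------------------------------------------

def tcr_recon(frames: list[KSpaceFrame], baseline_image: np.ndarray,
              consts: PRFSConstants, lambda_t: float | None = None,
              n_iters: int = 40, step_size: float | None = None,
              epsilon_l1: float = 1e-6, keep_images: bool = False) -> ReconResult:
    """Temporally constrained reconstruction by backtracking gradient descent.

    Minimizes C(m) = sum_t ||mask*F(m_t) - d_t||^2
                   + lambda * sum_voxels sum_t sqrt(|m_{t+1} - m_t|^2 + eps^2)
    starting from the sliding-window initialization.  ``lambda_t`` defaults
    to 0.1 times the median magnitude of the acquired samples (dimensionally
    an image amplitude, balancing the two terms for unit-scale data).
    """
    if len(frames) < 2:
        raise ValueError("TCR needs at least 2 frames")
    _check_frames(frames)
    if n_iters < 0 or (step_size is not None and step_size <= 0):
        raise ValueError("invalid iteration budget or step size")
    if lambda_t is not None and lambda_t < 0:
        raise ValueError("lambda_t must be non-negative")
    d = np.stack([f.data for f in frames])
    masks = np.stack([np.broadcast_to(f.mask.pattern[None, :, :], f.data.shape)
                      for f in frames])
    if lambda_t is None:
        mags = np.abs(d[masks])
        lambda_t = 0.1 * float(np.median(mags[mags > 0])) if mags.size else 0.0
    sw = sliding_window_recon(frames, baseline_image, consts, keep_images=True)
    m = sw.images.astype(complex)
    eps2 = epsilon_l1 ** 2

    def cost_and_grad(m):
        km = np.stack([fft3c(m[t]) for t in range(m.shape[0])])
        resid = np.where(masks, km, 0.0) - d
        fid = float(np.sum(np.abs(resid) ** 2))
        g = np.stack([ifft3c(np.where(masks[t], resid[t], 0.0))
                      for t in range(m.shape[0])]) * 2.0
        diff = m[1:] - m[:-1]
        s = np.sqrt(np.abs(diff) ** 2 + eps2)
        pen = lambda_t * float(np.sum(s))
        gt = np.zeros_like(m)
        gt[:-1] -= diff / s
        gt[1:] += diff / s
        g = g + lambda_t * gt
        return fid + pen, g

    cost, g = cost_and_grad(m)
    trace = [cost]
    step = step_size if step_size is not None else 0.4  # < 1/L of the fidelity
    for _ in range(n_iters):
        gnorm2 = float(np.sum(np.abs(g) ** 2))
        if gnorm2 == 0.0:
            break
        accepted = False
        for _bt in range(30):
            m_new = m - step * g
            c_new, g_new = cost_and_grad(m_new)
            if c_new <= cost - 0.25 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            if c_new > cost * (1 + 1e-9):
                break  # no descent direction at machine precision
            m_new, c_new, g_new = m, cost, g
            break
        m, cost, g = m_new, c_new, g_new
        trace.append(cost)
        step *= 1.4  # allow the step to grow back
    dTs = np.stack([_dT_from_image(m[t], baseline_image, consts)
                    for t in range(m.shape[0])])
    series = TemperatureSeries(frames=dTs,
                               times=np.asarray([f.t_center for f in frames]),
                               spacing=(1.0, 1.0, 1.0))
    return ReconResult(series=series, method="tcr",
                       diagnostics={"cost_trace": trace, "lambda_t": lambda_t,
                                    "iterations": len(trace) - 1},
                       images=m if keep_images else None)
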