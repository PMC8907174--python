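"""Synthetic EDI-OCT phantoms and synthetic per-eye cohorts.

Two seeded generators make every pipeline stage testable without any real
acquisition.  ``generate_phantom_volume`` builds a B-scan stack containing a
choroid band of bright stroma with dark elliptical vessel lumina whose pixel
fraction is driven to a known target, so the ground-truth luminal mask (and
hence the true CVI) is exact; noise is applied only after the mask is
captured.  ``generate_cohort`` draws per-eye CVI/SFCT/covariate records with
the first and second moments of a published healthy-eye cohort, optionally
injecting linear covariate effects for power/calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import ValidationError
from .io import BScan, ChoroidBoundaries, VolumeScan


@dataclass
class PhantomSpec:
    """Geometry, optics, texture, and noise of a synthetic macular volume.

    The choroid is a flat band starting at row ``upper_depth`` with thickness
    ``thickness_um`` (scalar, or one value per scan to emulate a thickness
    range).  ``target_cvi`` is the ground-truth luminal pixel fraction; lumen
    ellipses with semi-axes drawn from ``lumen_radius_px`` are placed by
    rejection sampling until every scan's fraction is within
    ``fraction_tol`` of the target.  ``identical_scans`` reuses one lumen
    layout for all scans, making the per-scan fraction exactly constant.
    Noise: additive Gaussian (``noise_sd``, intensity units) and a
    multiplicative Rayleigh speckle component mixed in with weight
    ``speckle`` in [0, 1].  The seed fully determines the output.
    """

    n_scans: int = 31
    rows: int = 256
    cols: int = 512
    scale_x: float = 0.0116
    scale_y: float = 0.0039
    spacing_um: float = 240.0
    upper_depth: int = 100
    thickness_um: float | Sequence[float] = 288.0
    target_cvi: float = 0.62
    lumen_radius_px: tuple[float, float] = (2.0, 6.0)
    stroma_level: int = 220
    lumen_level: int = 30
    background_level: int = 130
    noise_sd: float = 0.0
    speckle: float = 0.0
    fraction_tol: float = 0.005
    identical_scans: bool = False
    signal_strength: float = 30.0
    fovea_index: int | None = None
    eye_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_cvi < 1.0:
            raise ValidationError("target_cvi must lie strictly between 0 and 1")
        if not 0.0 <= self.speckle <= 1.0:
            raise ValidationError("speckle mix weight must lie in [0, 1]")

    def thickness_per_scan(self) -> np.ndarray:
        t = np.atleast_1d(np.asarray(self.thickness_um, dtype=float))
        if t.size == 1:
            t = np.full(self.n_scans, t[0])
        if t.size != self.n_scans:
            raise ValidationError("thickness_um must be scalar or one per scan")
        return t


def _fill_lumina(
    rng: np.random.Generator,
    band_rows: tuple[int, int],
    cols: int,
    target: float,
    tol: float,
    radii: tuple[float, float],
) -> np.ndarray:
    """Place dark ellipses inside the band until the covered fraction lies in
    [target - tol, target + tol]; raises if the target is unreachable."""
    u, l = band_rows
    band_area = (l - u) * cols
    lum = np.zeros((l - u, cols), dtype=bool)
    count = 0
    lo_count = (target - tol) * band_area
    hi_count = (target + tol) * band_area
    max_attempts = 200 * max(int(band_area * target / 20), 100)
    attempts = 0
    yy = np.arange(l - u)[:, None]
    while count < lo_count:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                "could not reach target luminal fraction with the given "
                "ellipse sizes; widen fraction_tol or shrink the radii"
            )
        cy = rng.uniform(0, l - u)
        cx = rng.uniform(0, cols)
        a = rng.uniform(*radii)
        b = rng.uniform(*radii)
        r0, r1 = max(0, int(cy - a) - 1), min(l - u, int(cy + a) + 2)
        c0, c1 = max(0, int(cx - b) - 1), min(cols, int(cx + b) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        yy_p = np.arange(r0, r1)[:, None]
        xx_p = np.arange(c0, c1)[None, :]
        patch = ((yy_p - cy) / a) ** 2 + ((xx_p - cx) / b) ** 2 <= 1.0
        new = patch & ~lum[r0:r1, c0:c1]
        gain = int(new.sum())
        if gain and count + gain <= hi_count:
            lum[r0:r1, c0:c1] |= patch
            count += gain
    return lum


def generate_phantom_volume(
    spec: PhantomSpec,
) -> tuple[VolumeScan, ChoroidBoundaries, list[np.ndarray]]:
    """Build a phantom volume with exact ground truth.

    Returns the volume, its choroid boundaries (emitted exactly as
    constructed), and the per-scan ground-truth luminal masks captured
    before noise is applied — so |estimated - target| measures binarisation
    error alone.
    """
    rng = np.random.default_rng(spec.seed)
    thickness = spec.thickness_per_scan()
    u = spec.upper_depth
    scans: list[BScan] = []
    uppers = np.empty((spec.n_scans, spec.cols), dtype=int)
    lowers = np.empty((spec.n_scans, spec.cols), dtype=int)
    truth_masks: list[np.ndarray] = []

    shared_lum: np.ndarray | None = None
    for s in range(spec.n_scans):
        t_px = int(round(thickness[s] / 1000.0 / spec.scale_y))
        l = u + t_px
        if l > spec.rows:
            raise ValidationError("choroid band does not fit in the image")
        if spec.identical_scans:
            if shared_lum is None:
                shared_lum = _fill_lumina(
                    rng, (u, l), spec.cols, spec.target_cvi,
                    spec.fraction_tol, spec.lumen_radius_px,
                )
            lum_band = shared_lum
        else:
            lum_band = _fill_lumina(
                rng, (u, l), spec.cols, spec.target_cvi,
                spec.fraction_tol, spec.lumen_radius_px,
            )

        img = np.full((spec.rows, spec.cols), spec.background_level, dtype=np.float64)
        # cosmetic retina/RPE bands above the choroid; never enter any measurement
        retina_top = max(0, u - 60)
        img[retina_top : max(0, u - 12)] = 170
        img[max(0, u - 12) : u] = 235
        img[u:l] = spec.stroma_level
        band_mask = np.zeros((spec.rows, spec.cols), dtype=bool)
        band_mask[u:l] = lum_band
        img[band_mask] = spec.lumen_level
        truth_masks.append(band_mask)

        if spec.speckle > 0:
            rayleigh = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=img.shape)
            img = img * (1.0 + spec.speckle * (rayleigh - 1.0))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

        scans.append(
            BScan(pixels=pixels, scale_x=spec.scale_x, scale_y=spec.scale_y, index=s + 1)
        )
        uppers[s] = u
        lowers[s] = l

    fovea = spec.fovea_index if spec.fovea_index is not None else spec.n_scans // 2 + 1
    volume = VolumeScan(
        scans=scans,
        spacing_um=spec.spacing_um,
        fovea_index=fovea,
        signal_strength=spec.signal_strength,
        eye_id=spec.eye_id,
    )
    boundaries = ChoroidBoundaries(upper=uppers, lower=lowers)
    return volume, boundaries, truth_masks


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic per-eye cohort.

    CVI measures are drawn around the published overall moments through a
    shared latent per-eye factor (correlation ``rho`` between any two
    measures), SFCT from its published mean/SD, and covariates from the
    standard battery.  ``effects`` maps covariate name to a linear slope on
    ``outcome``; effect covariates are mean-centred before being added so
    the outcome's marginal mean stays at its specified value.  With no
    effects, every covariate is independent of every outcome (a null
    cohort).  The seed fully determines the table.
    """

    n_eyes: int = 50
    cvi_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            **reference.CVI_OVERALL,
            **reference.CVI_SUBSET_MEANS,
        }
    )
    sfct_moments: tuple[float, float] = reference.SFCT_OVERALL
    rho: float = 0.7
    covariates: Mapping[str, tuple] = field(
        default_factory=lambda: dict(reference.COVARIATES)
    )
    effects: Mapping[str, float] = field(default_factory=dict)
    outcome: str = "cvi3d_whole"
    seed: int = 0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a seeded cohort table matching the statistics-layer schema."""
    if spec.n_eyes < 1:
        raise ValidationError("n_eyes must be positive")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_eyes
    data: dict = {"eye_id": [f"eye{i:04d}" for i in range(1, n + 1)]}

    latent = rng.normal(size=n)
    rho = spec.rho
    for name, (mean, sd) in spec.cvi_moments.items():
        eps = rng.normal(size=n)
        data[name] = mean + sd * (rho * latent + np.sqrt(1 - rho**2) * eps)

    sf_mean, sf_sd = spec.sfct_moments
    data["sfct_um"] = np.maximum(rng.normal(sf_mean, sf_sd, size=n), 50.0)

    for name, (kind, params) in spec.covariates.items():
        if kind == "normal":
            data[name] = rng.normal(params[0], params[1], size=n)
        elif kind == "binary":
            data[name] = (rng.uniform(size=n) < params).astype(int)
        elif kind == "categorical":
            levels = list(params.keys())
            probs = np.asarray(list(params.values()), dtype=float)
            data[name] = rng.choice(levels, size=n, p=probs / probs.sum())
        else:
            raise ValidationError(f"unknown covariate kind {kind!r}")

    df = pd.DataFrame(data)
    if spec.effects:
        shift = np.zeros(n)
        for name, beta in spec.effects.items():
            x = df[name].to_numpy(dtype=float)
            shift += beta * (x - x.mean())
        df[spec.outcome] = df[spec.outcome].to_numpy() + shift
    return df
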