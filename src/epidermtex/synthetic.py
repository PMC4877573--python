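"""Seeded generators of epidermis-like texture images and trait tables.

Real abaxial epidermis micrographs show a mosaic of pavement cells (bright
interiors, darker anticlinal walls) peppered with elliptical stomatal
complexes.  The generator emulates exactly the features the descriptor
families respond to, without claiming biological realism:

* a jittered-seed nearest-region cell mosaic with darkened boundaries
  (local contrast steps -> corrosion automaton, micro-patterns -> LBP);
* additive 1/f^alpha spectral noise (radial energy profile -> Fourier
  circular rings);
* anti-aliased dark stomatal ellipses with a lighter pore slit, with
  controllable density, axis lengths and orientation concentration
  (oriented structure -> Fourier wedges; their realized values are the
  "manually measured" stomatal traits).

A *plasticity shift* rescales the trait parameters (density, length, width)
of a species for a second simulated environment while leaving the
micro-texture parameters (mosaic scale, spectral exponent) untouched, so
texture descriptors stay informative while manual traits drift — the
scenario used to probe robustness to phenotypic plasticity.

Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .imaging import MAX_LEVEL


@dataclass(frozen=True)
class SpeciesModel:
    """Generative parameters of one simulated species.

    Trait parameters: ``stomata_density`` is the expected stoma count per
    image (Poisson); axis lengths are truncated normals in final-resolution
    pixels; ``orientation_concentration`` is a von Mises kappa (0 = uniform
    orientations).  Micro-texture parameters: ``mosaic_cell_scale`` is the
    pavement-cell spacing in pixels, ``spectral_exponent`` the power-law
    slope alpha of the 1/f^alpha background noise, ``base_intensity`` and
    ``noise_contrast`` intensity units.
    """

    name: str = "species"
    stomata_density: float = 40.0
    stomata_length_mean: float = 20.0
    stomata_length_std: float = 1.5
    stomata_width_mean: float = 12.0
    stomata_width_std: float = 1.0
    orientation_concentration: float = 0.0
    mosaic_cell_scale: float = 16.0
    spectral_exponent: float = 1.5
    base_intensity: float = 150.0
    noise_contrast: float = 15.0

    def __post_init__(self):
        if self.stomata_density < 0:
            raise ValueError("stomata density must be >= 0")
        if not (self.stomata_length_mean >= self.stomata_width_mean > 0):
            raise ValueError("require length_mean >= width_mean > 0")
        if self.stomata_length_std < 0 or self.stomata_width_std < 0:
            raise ValueError("axis stds must be >= 0")
        if self.mosaic_cell_scale <= 0:
            raise ValueError("mosaic cell scale must be > 0")
        if self.orientation_concentration < 0:
            raise ValueError("orientation concentration must be >= 0")


@dataclass(frozen=True)
class PlasticityShift:
    """Multiplicative trait shifts for a second environment."""

    density_factor: float = 1.0
    length_factor: float = 1.0
    width_factor: float = 1.0

    def __post_init__(self):
        if min(self.density_factor, self.length_factor, self.width_factor) <= 0:
            raise ValueError("shift factors must be > 0")

    def apply(self, model: SpeciesModel) -> SpeciesModel:
        """Shifted copy of a species model; micro-texture untouched."""
        lf, wf = self.length_factor, self.width_factor
        length = model.stomata_length_mean * lf
        width = model.stomata_width_mean * wf
        if length < width:  # keep the model's axis invariant intact
            length = width
        return replace(
            model,
            stomata_density=model.stomata_density * self.density_factor,
            stomata_length_mean=length,
            stomata_length_std=model.stomata_length_std * lf,
            stomata_width_mean=width,
            stomata_width_std=model.stomata_width_std * wf,
        )


def _truncated_normal(rng, mean, std, size):
    if std == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / std
    return truncnorm.rvs(a, np.inf, loc=mean, scale=std, size=size, random_state=rng)


def _cell_mosaic(rng, shape, spacing, wall_depth=35.0, shade_amp=8.0):
    """Jittered-grid nearest-region mosaic with darker boundaries."""
    h, w = shape
    gi = np.arange(spacing / 2, h, spacing)
    gj = np.arange(spacing / 2, w, spacing)
    pts = np.stack(np.meshgrid(gi, gj, indexing="ij"), axis=-1).reshape(-1, 2)
    pts = pts + rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    tree = cKDTree(pts)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel()], axis=1)
    _, label = tree.query(coords, workers=1)
    label = label.reshape(h, w)
    shade = rng.uniform(-shade_amp, shade_amp, size=len(pts))[label]
    boundary = np.zeros(shape, dtype=bool)
    boundary[:-1, :] |= label[:-1, :] != label[1:, :]
    boundary[1:, :] |= label[1:, :] != label[:-1, :]
    boundary[:, :-1] |= label[:, :-1] != label[:, 1:]
    boundary[:, 1:] |= label[:, 1:] != label[:, :-1]
    return shade - wall_depth * boundary


def _spectral_noise(rng, shape, exponent):
    """Zero-mean unit-std noise with a 1/f^exponent power spectrum."""
    h, w = shape
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-exponent / 2.0)
    field = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    sd = field.std()
    return field / sd if sd > 0 else field


def _paint_stomata(rng, canvas, model, ss):
    """Rasterise Poisson-count dark ellipses with a lighter pore slit.

    Returns (count, realized lengths, realized widths) in final-resolution
    pixels.
    """
    h, w = canvas.shape
    count = int(rng.poisson(model.stomata_density))
    lengths = _truncated_normal(rng, model.stomata_length_mean, model.stomata_length_std, count)
    widths = _truncated_normal(rng, model.stomata_width_mean, model.stomata_width_std, count)
    if model.orientation_concentration > 0:
        thetas = rng.vonmises(0.0, model.orientation_concentration, size=count)
    else:
        thetas = rng.uniform(0.0, 2.0 * np.pi, size=count)
    centers = np.stack(
        [rng.uniform(0, h, size=count), rng.uniform(0, w, size=count)], axis=1
    )
    depth, pore_lift = 70.0, 45.0
    for (ci, cj), L, W, th in zip(centers, lengths, widths, thetas):
        a, b = (L * ss) / 2.0, (W * ss) / 2.0
        ext = int(np.ceil(max(a, b))) + 1
        i0, i1 = max(0, int(ci) - ext), min(h, int(ci) + ext + 1)
        j0, j1 = max(0, int(cj) - ext), min(w, int(cj) + ext + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        yy = np.arange(i0, i1)[:, None] - ci
        xx = np.arange(j0, j1)[None, :] - cj
        u = (xx * np.cos(th) + yy * np.sin(th)) / a
        v = (-xx * np.sin(th) + yy * np.cos(th)) / b
        r2 = u * u + v * v
        patch = canvas[i0:i1, j0:j1]
        patch[r2 <= 1.0] -= depth
        pore = (u / 0.8) ** 2 + (v / 0.25) ** 2
        patch[pore <= 1.0] += pore_lift
    return count, lengths, widths


def generate_image(
    model: SpeciesModel,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    supersample: int = 2,
) -> tuple[np.ndarray, dict]:
    """One seeded epidermis-like image plus its realized trait vector.

    The scene is rendered at ``supersample`` times the target resolution and
    box-downsampled, so ellipse edges are anti-aliased rather than jagged.
    The trait dict holds the realized stoma count (``density``) and the mean
    realized axis lengths in final-resolution pixels (zero when no stomata
    were drawn).
    """
    M, N = size
    if M < 64 or N < 64:
        raise ValueError(f"minimum size is 64x64, got {size}")
    rng = np.random.default_rng(seed)
    ss = int(supersample)
    shape = (M * ss, N * ss)

    canvas = np.full(shape, model.base_intensity, dtype=np.float64)
    canvas += _cell_mosaic(rng, shape, model.mosaic_cell_scale * ss)
    canvas += model.noise_contrast * _spectral_noise(rng, shape, model.spectral_exponent)
    count, lengths, widths = _paint_stomata(rng, canvas, model, ss)

    img = canvas.reshape(M, ss, N, ss).mean(axis=(1, 3))
    img = np.rint(np.clip(img, 0, MAX_LEVEL)).astype(np.int64)
    traits = {
        "density": float(count),
        "guard_cell_length": float(np.mean(lengths)) if count else 0.0,
        "complex_width": float(np.mean(widths)) if count else 0.0,
    }
    return img, traits


def generate_dataset(
    models: list[SpeciesModel],
    n_per_class: int,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    environment: str = "gallery_forest",
    id_prefix: str = "",
) -> tuple[list[np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Seeded images for each species plus label and trait tables.

    Returns ``(images, labels, traits)`` where ``labels`` has columns
    sample_id/species/environment and ``traits`` the three manual stomatal
    measurements per sample.  Per-image seeds are spawned deterministically
    from the master seed.
    """
    if len(models) < 1:
        raise ValueError("need at least one species model")
    streams = np.random.SeedSequence(seed).spawn(len(models) * n_per_class)
    images, label_rows, trait_rows = [], [], []
    idx = 0
    for model in models:
        for r in range(n_per_class):
            child_seed = int(streams[idx].generate_state(1)[0] % (2**31))
            img, traits = generate_image(model, size=size, seed=child_seed)
            sid = f"{id_prefix}{model.name}_{environment}_{r:03d}"
            images.append(img)
            label_rows.append(
                {"sample_id": sid, "species": model.name, "environment": environment}
            )
            trait_rows.append({"sample_id": sid, **traits})
            idx += 1
    return images, pd.DataFrame(label_rows), pd.DataFrame(trait_rows)


def generate_plasticity_pair(
    model: SpeciesModel,
    shift: PlasticityShift,
    n_env1: int,
    n_env2: int,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    env_names: tuple[str, str] = ("gallery_forest", "marsh_camp"),
):
    """Two same-species sample sets from different simulated environments.

    Environment 1 draws from ``model``; environment 2 from the trait-shifted
    copy (same class label, different environment tag, micro-texture
    parameters preserved).  Returns ``((images1, labels1, traits1),
    (images2, labels2, traits2))``.
    """
    ss1, ss2 = np.random.SeedSequence(seed).spawn(2)
    set1 = generate_dataset(
        [model], n_env1, size=size, seed=int(ss1.generate_state(1)[0] % (2**31)),
        environment=env_names[0],
    )
    set2 = generate_dataset(
        [shift.apply(model)], n_env2, size=size,
        seed=int(ss2.generate_state(1)[0] % (2**31)), environment=env_names[1],
    )
    return set1, set2


#: geometric pavement-cell spacings (px): each species' mosaic peaks at a
#: distinct spectral ring (radius ~ image_size / spacing)
_MOSAIC_SCALES = (6.0, 8.0, 11.0, 15.0, 20.0, 27.0, 36.0, 44.0)
#: alternating low/high power-law slopes so neighbouring spacings also
#: differ in their broadband radial profile
_SPECTRAL_EXPONENTS = (1.0, 2.6, 1.2, 3.0, 1.5, 3.4, 1.3, 2.2)
#: alternating noise amplitudes (intensity units) reinforcing the contrast
#: between species that share similar spacings or slopes
_NOISE_CONTRASTS = (8.0, 18.0, 10.0, 22.0, 12.0, 26.0, 14.0, 34.0)


def well_separated_models(n: int = 8) -> list[SpeciesModel]:
    """A panel of species models with well-separated parameters.

    Micro-texture parameters combine geometrically spaced mosaic scales
    with alternating spectral exponents, so each species has a distinctive
    radial energy profile; trait parameters (density, axis lengths) step
    monotonically so manual traits are informative on their own; orientation
    concentration alternates so the wedge features also see structure.
    """
    models = []
    for i in range(n):
        models.append(
            SpeciesModel(
                name=f"species_{i:02d}",
                stomata_density=15.0 + 5.0 * i,
                stomata_length_mean=12.0 + 2.0 * i,
                stomata_length_std=1.0,
                stomata_width_mean=8.0 + 1.2 * i,
                stomata_width_std=0.7,
                orientation_concentration=0.0 if i % 2 == 0 else 4.0,
                mosaic_cell_scale=_MOSAIC_SCALES[i % len(_MOSAIC_SCALES)],
                spectral_exponent=_SPECTRAL_EXPONENTS[i % len(_SPECTRAL_EXPONENTS)],
                base_intensity=150.0,
                noise_contrast=_NOISE_CONTRASTS[i % len(_NOISE_CONTRASTS)],
            )
        )
    return models
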