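"""Stimulus construction for the backward-masking face paradigm.

Four matched stimulus classes are built per face exemplar:

* the face itself, restricted to an oval cutout with a Gaussian-blurred edge;
* a *mask*, made by cutting the oval face region into 10 x 10 pixel squares
  and permuting them randomly;
* a *blank*, a homogeneous oval filled with the average RGB color of the
  face's oval region (matched in mean color/luminance, no contrast);
* a *scramble*, whose Fourier amplitude spectrum inside the oval target
  region matches the face's while the phase content is randomized (matched
  in mean color *and* contrast, no configural face content).

Real face databases are replaced by :func:`synth_face`, a procedural
face-like image generator used as a fixture throughout.

Conventions: pixel arrays are ``(rows, cols, 3)`` uint8; all geometry is
0-based ``(row, col)`` internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "OvalSpec",
    "ScrambleParams",
    "make_oval_alpha",
    "make_blank",
    "make_mask_stimulus",
    "make_scramble",
    "synth_face",
    "generate_stimulus_set",
    "oval_mean_color",
    "windowed_spectrum_distance",
]


@dataclass(frozen=True)
class OvalSpec:
    """Oval cutout geometry: center (row, col), semi-axes (a=rows, b=cols),
    and the Gaussian sigma (pixels) of the edge transition."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    blur_sigma: float = 4.0

    def validate(self, shape: tuple[int, int]) -> None:
        a, b = self.semi_axes
        r, c = self.center
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if r - a < 0 or r + a > shape[0] - 1 or c - b < 0 or c + b > shape[1] - 1:
            raise ValueError(f"oval {self} exceeds image bounds {shape}")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open, of the unblurred ellipse."""
        r, c = self.center
        a, b = self.semi_axes
        return (
            int(np.floor(r - a)),
            int(np.ceil(r + a)) + 1,
            int(np.floor(c - b)),
            int(np.ceil(c + b)) + 1,
        )


@dataclass(frozen=True)
class ScrambleParams:
    """Controls the alternating-projection spectrum-matching loop."""

    n_iterations: int = 200
    spectral_tolerance: float = 0.01
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.spectral_tolerance <= 0:
            raise ValueError("spectral_tolerance must be > 0")


def make_oval_alpha(shape: tuple[int, int], oval: OvalSpec) -> np.ndarray:
    """Soft oval alpha map in [0, 1]: 1 in the oval core, 0 far outside,
    with a Gaussian-blurred transition of width ``blur_sigma``."""
    oval.validate(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = oval.center
    a, b = oval.semi_axes
    inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    alpha = inside.astype(float)
    if oval.blur_sigma > 0:
        alpha = gaussian_filter(alpha, sigma=oval.blur_sigma, mode="constant")
        np.clip(alpha, 0.0, 1.0, out=alpha)
    return alpha


def _composite(content: np.ndarray, face: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Blend float ``content`` into ``face``'s background through ``alpha``."""
    out = alpha[..., None] * content + (1.0 - alpha[..., None]) * face.astype(float)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def oval_mean_color(face: np.ndarray, oval: OvalSpec) -> np.ndarray:
    """Alpha-weighted mean RGB of the oval region (float, length 3)."""
    alpha = make_oval_alpha(face.shape[:2], oval)
    w = alpha.sum()
    return (alpha[..., None] * face.astype(float)).sum(axis=(0, 1)) / w


def make_blank(face: np.ndarray, oval: OvalSpec) -> np.ndarray:
    """Homogeneous oval of the face's average oval-region RGB color, with the
    same cutout and edge blur applied.

    The fill color is the alpha^2-weighted mean of the face: because the
    soft cutout blends the fill with the background by ``alpha``, this is
    the unique constant whose *composite* has exactly the same alpha-
    weighted oval mean color as the face itself (the matched-mean
    invariant of the stimulus quadruple).  For any uniform face it reduces
    to that color.
    """
    alpha = make_oval_alpha(face.shape[:2], oval)
    w2 = alpha**2
    color = (w2[..., None] * face.astype(float)).sum(axis=(0, 1)) / w2.sum()
    content = np.broadcast_to(color, face.shape)
    return _composite(content, face, alpha)


def make_mask_stimulus(
    face: np.ndarray,
    oval: OvalSpec,
    block_px: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Block-scramble mask: the oval's bounding grid of ``block_px`` squares
    is randomly permuted, then re-cut with the same oval alpha.

    Only blocks lying completely inside the bounding box take part in the
    permutation; partial edge blocks are left in place.
    """
    oval.validate(face.shape[:2])
    r0, r1, c0, c1 = oval.bounding_box()
    if block_px <= 0:
        raise ValueError("block_px must be positive")
    n_br, n_bc = (r1 - r0) // block_px, (c1 - c0) // block_px
    if n_br < 1 or n_bc < 1:
        raise ValueError("block_px larger than the oval bounding box")
    rng = np.random.default_rng(seed)
    region = face[r0 : r0 + n_br * block_px, c0 : c0 + n_bc * block_px].astype(float)
    blocks = region.reshape(n_br, block_px, n_bc, block_px, 3).transpose(0, 2, 1, 3, 4)
    flat = blocks.reshape(n_br * n_bc, block_px, block_px, 3)
    flat = flat[rng.permutation(n_br * n_bc)]
    blocks = flat.reshape(n_br, n_bc, block_px, block_px, 3).transpose(0, 2, 1, 3, 4)
    content = face.astype(float).copy()
    content[r0 : r0 + n_br * block_px, c0 : c0 + n_bc * block_px] = blocks.reshape(
        n_br * block_px, n_bc * block_px, 3
    )
    alpha = make_oval_alpha(face.shape[:2], oval)
    return _composite(content, face, alpha)


def _windowed_amplitude(img: np.ndarray, alpha: np.ndarray, bbox) -> np.ndarray:
    """Per-channel 2-D FFT amplitude of the alpha-windowed oval bounding box."""
    r0, r1, c0, c1 = bbox
    w = alpha[r0:r1, c0:c1, None]
    u = w * img[r0:r1, c0:c1].astype(float)
    return np.abs(np.fft.fft2(u, axes=(0, 1)))


def windowed_spectrum_distance(
    a: np.ndarray, b: np.ndarray, oval: OvalSpec
) -> float:
    """Relative L2 distance between oval-windowed amplitude spectra of two
    images (pooled over the three color channels)."""
    alpha = make_oval_alpha(a.shape[:2], oval)
    bbox = oval.bounding_box()
    fa = _windowed_amplitude(a, alpha, bbox)
    fb = _windowed_amplitude(b, alpha, bbox)
    return float(np.linalg.norm(fa - fb) / np.linalg.norm(fa))


def make_scramble(
    face: np.ndarray,
    oval: OvalSpec,
    params: ScrambleParams = ScrambleParams(),
) -> tuple[np.ndarray, dict]:
    """Spectrum-matched scramble of the oval face region.

    The windowed spectrum of any stimulus splits into a shared, deterministic
    part ``M`` (the alpha window times the oval mean color) and the content
    deviation ``D``.  A scramble must reproduce the total amplitude
    ``A = |M + D|`` per frequency bin while randomizing phase.  Two regimes
    exist per bin:

    * where the deviation dominates (``|D| >= |M|``), every total phase is
      attainable: draw a uniform phase ``theta`` and set
      ``X = -M + A*exp(i*theta)`` (exact amplitude, fully random phase);
    * where the window term dominates (``|M| > |D|``), the amplitude
      constraint pins the deviation up to a mirror reflection about the
      window phase; the reflection sign is drawn at random.

    The resulting deviation field is added to the mean color, clipped to
    [0, 255], and refined by a few alternating-projection sweeps (impose
    target amplitude in frequency; clip, restore mean color, and re-composite
    in space) until the relative amplitude distance of the rounded 8-bit
    composite is within ``spectral_tolerance``.  Non-convergence within
    ``n_iterations`` returns the best iterate with ``converged=False`` and
    the achieved distance.

    Returns ``(image, info)``; ``info`` holds ``achieved_distance``,
    ``iterations`` and ``converged``.
    """
    oval.validate(face.shape[:2])
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    alpha = make_oval_alpha(face.shape[:2], oval)
    bbox = oval.bounding_box()
    r0, r1, c0, c1 = bbox
    w = alpha[r0:r1, c0:c1]
    wsum = w.sum()
    f = face[r0:r1, c0:c1].astype(float)
    mean_color = (w[..., None] * f).sum(axis=(0, 1)) / wsum
    M = np.fft.fft2(w)[..., None] * mean_color
    D = np.fft.fft2(w[..., None] * (f - mean_color), axes=(0, 1))
    A = np.abs(M + D)
    aM, aD = np.abs(M), np.abs(D)
    phiM = np.angle(M)

    with np.errstate(invalid="ignore", divide="ignore"):
        cos_rel = (A**2 - aM**2 - aD**2) / (2 * aM * aD)
    cos_rel = np.clip(np.nan_to_num(cos_rel, nan=0.0), -1.0, 1.0)
    rel = np.arccos(cos_rel)
    Z = np.fft.fft2(rng.normal(size=D.shape), axes=(0, 1))
    theta = np.angle(Z)  # conjugate-antisymmetric uniform phases
    sign = np.sign(Z.imag)  # antisymmetric random reflection signs
    window_dominated = aM > aD
    X = np.where(
        window_dominated,
        aD * np.exp(1j * (phiM + sign * rel)),
        -M + A * np.exp(1j * theta),
    )
    self_conj = np.abs(Z.imag) < 1e-12  # DC/Nyquist bins must stay real
    X[self_conj] = D[self_conj]

    content = np.clip(mean_color + np.fft.ifft2(X, axes=(0, 1)).real, 0, 255)
    alpha_bb = w[..., None]
    best: tuple[float, np.ndarray] | None = None
    n_done = 0
    for it in range(params.n_iterations):
        cur_mean = (alpha_bb * content).sum(axis=(0, 1)) / wsum
        content = np.clip(content + (mean_color - cur_mean), 0, 255)
        composite = alpha_bb * content + (1 - alpha_bb) * f
        rounded = np.clip(np.rint(composite), 0, 255)
        amp = np.abs(np.fft.fft2(alpha_bb * rounded, axes=(0, 1)))
        dist = float(np.linalg.norm(amp - A) / np.linalg.norm(A))
        n_done = it + 1
        if best is None or dist < best[0]:
            best = (dist, content.copy())
        if dist <= params.spectral_tolerance:
            break
        spec = np.fft.fft2(alpha_bb * composite, axes=(0, 1))
        v = np.fft.ifft2(A * np.exp(1j * np.angle(spec)), axes=(0, 1)).real
        upd = (v / np.maximum(w, 0.25)[..., None] - (1 - w)[..., None] * f) / np.maximum(
            w, 0.25
        )[..., None]
        content = np.clip(np.where(w[..., None] > 0.3, upd, content), 0, 255)

    dist, content = best
    # exact mean-color restoration of the composite: a DC shift on the
    # content weighted through the alpha blend
    composite = alpha_bb * content + (1 - alpha_bb) * f
    cur = (alpha_bb * composite).sum(axis=(0, 1)) / wsum
    target = (alpha_bb * f).sum(axis=(0, 1)) / wsum
    content = np.clip(content + (target - cur) * (wsum / (w**2).sum()), 0, 255)
    full = face.astype(float).copy()
    full[r0:r1, c0:c1] = content
    out = _composite(full, face, alpha)
    final_dist = windowed_spectrum_distance(face, out, oval)
    return out, {
        "achieved_distance": final_dist,
        "iterations": n_done,
        "converged": final_dist <= params.spectral_tolerance,
    }


def synth_face(
    seed: int,
    size: int = 256,
    palette: tuple[tuple[int, int, int], ...] = (
        (224, 188, 160),
        (198, 158, 128),
        (168, 126, 98),
    ),
) -> np.ndarray:
    """Procedural face-like fixture image: skin-tone oval, two darker eye
    blobs, a mouth bar, plus smooth random shading for spectral richness.

    Deterministic for a given seed; stands in for photographic face sets.
    """
    if size < 64:
        raise ValueError("size must be >= 64 to place facial features")
    rng = np.random.default_rng(seed)
    skin = np.array(palette[rng.integers(len(palette))], float)
    bg = 128.0
    img = np.full((size, size, 3), bg)
    rr, cc = np.mgrid[0:size, 0:size]
    r0 = c0 = size / 2
    a, b = 0.42 * size, 0.32 * size
    head = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0

    # multi-scale shading; most variance sits at mid/fine scales so the
    # spectrum is broadband, as in photographic faces
    def tex(sig: float, amp: float) -> np.ndarray:
        t = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=sig)
        return t * (amp / max(t.std(), 1e-9))

    shade = tex(size / 16, 4) + tex(size / 48, 6) + tex(2.0, 13) + tex(0.8, 14)
    for ch in range(3):
        img[..., ch][head] = skin[ch] + shade[head]
    eye_dr = -0.12 * size + rng.normal(0, 0.01 * size)
    eye_dc = 0.13 * size + rng.normal(0, 0.01 * size)
    eye_r = max(3, int(0.045 * size))
    eye_col = np.array([100, 76, 60], float) + rng.normal(0, 6, 3)
    for sgn in (-1, 1):
        er, ec = r0 + eye_dr, c0 + sgn * eye_dc
        blob = (rr - er) ** 2 + (cc - ec) ** 2 <= eye_r**2
        img[blob] = eye_col
    mr = int(r0 + 0.22 * size + rng.normal(0, 0.01 * size))
    half_w = int(0.12 * size)
    mh = max(2, int(0.02 * size))
    mouth_col = np.array([150, 80, 80], float) + rng.normal(0, 8, 3)
    img[mr : mr + mh, int(c0) - half_w : int(c0) + half_w] = mouth_col
    img = gaussian_filter(img, sigma=(1.0, 1.0, 0))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def default_oval(size: int) -> OvalSpec:
    """Oval matching :func:`synth_face` head placement."""
    return OvalSpec(
        center=(size / 2, size / 2),
        semi_axes=(0.42 * size, 0.32 * size),
        blur_sigma=max(2.0, size / 20),
    )


def generate_stimulus_set(
    n_exemplars: int = 80,
    size: int = 256,
    block_px: int = 10,
    seed: int = 0,
    out_dir: str | Path | None = None,
    scramble_params: ScrambleParams | None = None,
) -> "pd.DataFrame":
    """Build matched (face, mask, blank, scramble) quadruples for
    ``n_exemplars`` procedural faces.

    If ``out_dir`` is given, PNGs are written there and a manifest TSV
    (``stimuli.tsv``) maps exemplar_id to the four file paths and the oval
    geometry.  Returns the manifest as a DataFrame; when ``out_dir`` is None
    the images themselves are attached in extra columns.
    """
    import pandas as pd

    oval = default_oval(size)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_exemplars)
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i in range(n_exemplars):
        sub = np.random.default_rng(child[i])
        face_seed, mask_seed, scr_seed = (int(x) for x in sub.integers(0, 2**31 - 1, 3))
        face = synth_face(face_seed, size=size)
        mask = make_mask_stimulus(face, oval, block_px=block_px, seed=mask_seed)
        blank = make_blank(face, oval)
        sp = scramble_params or ScrambleParams(rng_seed=scr_seed)
        if scramble_params is not None:
            sp = ScrambleParams(sp.n_iterations, sp.spectral_tolerance, scr_seed)
        scramble, info = make_scramble(face, oval, sp)
        row = {
            "exemplar_id": i + 1,
            "oval_center_row": oval.center[0],
            "oval_center_col": oval.center[1],
            "oval_semi_a": oval.semi_axes[0],
            "oval_semi_b": oval.semi_axes[1],
            "oval_blur_sigma": oval.blur_sigma,
            "scramble_distance": info["achieved_distance"],
            "scramble_converged": info["converged"],
        }
        if out is not None:
            for name, arr in (
                ("face", face),
                ("mask", mask),
                ("blank", blank),
                ("scramble", scramble),
            ):
                p = out / f"{name}_{i + 1:03d}.png"
                Image.fromarray(arr).save(p)
                row[f"{name}_path"] = p.name
        else:
            row.update(face=face, mask=mask, blank=blank, scramble=scramble)
        rows.append(row)
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out / "stimuli.tsv", sep="\t", index=False)
    return df
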