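"""Synthetic fluorescence scenes with known ground truth.

Real striatal tissue images behind the analysis are not publicly deposited, so
every downstream stage is exercised on simulated scenes instead. A scene is a
fully specified world: astrocyte somata drawn from a homogeneous Poisson
process (wild-type-like, complete spatial randomness) or a Thomas/Neyman–Scott
clustered process (HD-model-like), rendered as Gaussian soma blobs on 8-bit
marker channels; a punctum field (aggregate-like) with reduced intensity inside
designated exclusion zones; elliptical white-matter fascicle masks; and the
generating parameters plus seed, so the same spec reproduces the scene
bit-for-bit.

Coordinates are continuous physical μm; rasterization happens only when a
channel is rendered. The pixel-grid convention is origin top-left with pixel
(row, col) centered at ``((col + 0.5) · p, (row + 0.5) · p)`` for pixel size
``p``. Rendering uses a fixed linear scale (1 AU = 1 gray level, clipped to
[0, 255]) rather than per-image normalization, so the fixed 8-bit thresholds
used downstream (70 for the astrocyte marker, 30 for puncta) sit on a stable
intensity scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as _draw_ellipse

from .spatial import PointPattern

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "simulate_poisson_pattern",
    "simulate_thomas_pattern",
    "render_channel",
    "generate_puncta_field",
    "fascicle_mask_from_specs",
    "build_scene",
    "wt_like_spec",
    "hd_like_spec",
    "write_scene",
    "read_scene_spec",
]


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    w, h = float(window[0]), float(window[1])
    if not (w > 0 and h > 0):
        raise ValueError(f"window must be strictly positive, got {window}")
    return w, h


def _grid_shape(window: tuple[float, float], pixel_size_um: float) -> tuple[int, int]:
    w, h = _check_window(window)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    ny, nx = round(h / pixel_size_um), round(w / pixel_size_um)
    if ny < 1 or nx < 1:
        raise ValueError(
            f"pixel_size_um={pixel_size_um} incompatible with window {window}"
        )
    return ny, nx


def simulate_poisson_pattern(
    intensity: float,
    window: tuple[float, float],
    seed: int | np.random.Generator,
) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern with ``intensity`` points/μm².

    The point count is Poisson(intensity × area) and coordinates are i.i.d.
    uniform in the window. This is the null model against which clustering is
    judged.
    """
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    w, h = _check_window(window)
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * w * h)
    pts = rng.uniform((0, 0), (w, h), size=(n, 2))
    return PointPattern(pts, (w, h))


def simulate_thomas_pattern(
    kappa: float,
    mu: float,
    sigma_um: float,
    window: tuple[float, float],
    seed: int | np.random.Generator,
    *,
    toroidal: bool = False,
    parent_points: np.ndarray | None = None,
) -> tuple[PointPattern, np.ndarray, np.ndarray]:
    """Thomas (Neyman–Scott) clustered pattern.

    Parents are Poisson(kappa × area) uniform in the window; each parent emits
    Poisson(mu) offspring displaced by an isotropic Gaussian with scale
    ``sigma_um``. Offspring landing outside the window are discarded (no
    wrapping) unless ``toroidal`` is set, which wraps them instead — useful
    when validating intensity calibrations without edge loss.

    ``parent_points`` overrides the Poisson parent layer with fixed parent
    locations (planted-cluster experiments).

    Returns ``(pattern, parent_ids, parents)`` where ``parent_ids[i]`` is the
    index into ``parents`` of the parent that emitted offspring ``i`` — the
    ground-truth cluster assignment.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if sigma_um < 0:
        raise ValueError(f"sigma_um must be >= 0, got {sigma_um}")
    w, h = _check_window(window)
    rng = np.random.default_rng(seed)
    if parent_points is None:
        n_parents = rng.poisson(kappa * w * h)
        parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))
    else:
        parents = np.asarray(parent_points, dtype=float).reshape(-1, 2)
    offspring = []
    ids = []
    for j, p in enumerate(parents):
        k = rng.poisson(mu)
        if k == 0:
            continue
        pts = p + rng.normal(0.0, sigma_um, size=(k, 2))
        if toroidal:
            pts[:, 0] %= w
            pts[:, 1] %= h
        else:
            inside = (
                (pts[:, 0] >= 0) & (pts[:, 0] <= w)
                & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
            )
            pts = pts[inside]
        offspring.append(pts)
        ids.extend([j] * len(pts))
    pts = np.concatenate(offspring) if offspring else np.empty((0, 2))
    return PointPattern(pts, (w, h)), np.asarray(ids, dtype=int), parents


def render_channel(
    points: PointPattern,
    soma_sigma_um: float,
    amplitude: float,
    background: float,
    noise_sd: float,
    pixel_size_um: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Render a point pattern as an 8-bit fluorescence channel.

    Each point contributes an isotropic Gaussian blob
    ``amplitude · exp(−r²/(2σ²))`` on top of a flat background, plus i.i.d.
    Gaussian read noise; the sum is clipped to [0, 255] and quantized to uint8
    on a fixed linear scale (no per-image rescaling). The peak of an isolated
    blob is therefore ≈ background + amplitude.
    """
    if amplitude <= 0:
        raise ValueError(f"amplitude must be > 0, got {amplitude}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    ny, nx = _grid_shape(points.window, pixel_size_um)
    img = np.full((ny, nx), float(background))
    sigma_px = soma_sigma_um / pixel_size_um
    halo = max(1, int(np.ceil(4 * sigma_px)))
    for x_um, y_um in points.points:
        # pixel-center convention: pixel (r, c) center at ((c+.5)p, (r+.5)p)
        cx = x_um / pixel_size_um - 0.5
        cy = y_um / pixel_size_um - 0.5
        c0, c1 = max(0, int(cx) - halo), min(nx, int(cx) + halo + 2)
        r0, r1 = max(0, int(cy) - halo), min(ny, int(cy) + halo + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = np.arange(c0, c1)
        rr = np.arange(r0, r1)
        d2 = (cc[None, :] - cx) ** 2 + (rr[:, None] - cy) ** 2
        img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2 * sigma_px**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_disks(
    points: PointPattern,
    radius_um: float,
    pixel_size_um: float,
    value: int = 255,
) -> np.ndarray:
    """Render points as exact binary disks (uint8, 0/value).

    Counterpart of :func:`render_channel` for validation scenes where the
    object geometry must be known exactly: the rasterized disk of each soma is
    the set of pixels whose centers lie within ``radius_um`` of the point.
    """
    if radius_um < 0:
        raise ValueError(f"radius_um must be >= 0, got {radius_um}")
    ny, nx = _grid_shape(points.window, pixel_size_um)
    img = np.zeros((ny, nx), dtype=np.uint8)
    r_px = radius_um / pixel_size_um
    halo = int(np.ceil(r_px)) + 1
    for x_um, y_um in points.points:
        cx = x_um / pixel_size_um - 0.5
        cy = y_um / pixel_size_um - 0.5
        c0, c1 = max(0, int(cx) - halo), min(nx, int(cx) + halo + 2)
        r0, r1 = max(0, int(cy) - halo), min(ny, int(cy) + halo + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = np.arange(c0, c1)
        rr = np.arange(r0, r1)
        d2 = (cc[None, :] - cx) ** 2 + (rr[:, None] - cy) ** 2
        img[r0:r1, c0:c1][d2 <= r_px**2] = value
    return img


def generate_puncta_field(
    density_in: float,
    density_out: float,
    exclusion_mask: np.ndarray | None,
    window: tuple[float, float],
    pixel_size_um: float,
    seed: int | np.random.Generator,
) -> PointPattern:
    """Inhomogeneous Poisson punctum field over a binary compartment mask.

    Intensity is ``density_in`` points/μm² on the mask and ``density_out`` off
    it (an all-False or missing mask reduces to a homogeneous process at
    ``density_out``). Implemented by superposing two homogeneous processes and
    keeping each point according to the mask value at its pixel, which yields
    the exact piecewise-constant intensity.
    """
    if density_in < 0 or density_out < 0:
        raise ValueError("puncta densities must be >= 0")
    w, h = _check_window(window)
    rng = np.random.default_rng(seed)
    if exclusion_mask is None:
        return simulate_poisson_pattern(density_out, window, rng)
    mask = np.asarray(exclusion_mask, dtype=bool)
    if mask.shape != _grid_shape(window, pixel_size_um):
        raise ValueError(
            f"mask shape {mask.shape} does not match window {window} at "
            f"{pixel_size_um} μm/px"
        )

    def _on_mask(pts: np.ndarray) -> np.ndarray:
        col = np.clip((pts[:, 0] / pixel_size_um).astype(int), 0, mask.shape[1] - 1)
        row = np.clip((pts[:, 1] / pixel_size_um).astype(int), 0, mask.shape[0] - 1)
        return mask[row, col]

    inside = simulate_poisson_pattern(density_in, window, rng).points
    inside = inside[_on_mask(inside)] if len(inside) else inside
    outside = simulate_poisson_pattern(density_out, window, rng).points
    outside = outside[~_on_mask(outside)] if len(outside) else outside
    pts = np.concatenate([inside, outside]) if len(inside) or len(outside) else np.empty((0, 2))
    return PointPattern(pts, (w, h))


def fascicle_mask_from_specs(
    fascicle_specs: list[tuple],
    window: tuple[float, float],
    pixel_size_um: float,
) -> np.ndarray:
    """Rasterize elliptical fascicle cross-sections into a binary mask.

    Each spec is ``((cx_um, cy_um), (a_um, b_um), theta_rad)`` — center,
    semi-axes and orientation of one ellipse.
    """
    ny, nx = _grid_shape(window, pixel_size_um)
    mask = np.zeros((ny, nx), dtype=bool)
    for (cx, cy), (a, b), theta in fascicle_specs:
        rr, cc = _draw_ellipse(
            cy / pixel_size_um - 0.5,
            cx / pixel_size_um - 0.5,
            a / pixel_size_um,
            b / pixel_size_um,
            shape=(ny, nx),
            rotation=float(theta),
        )
        mask[rr, cc] = True
    return mask


# -- full scenes ----------------------------------------------------------

#: default render settings; amplitudes chosen so the fixed 8-bit thresholds
#: (70 astrocyte channel, 30 puncta channel) cut soma blobs at ~7 μm diameter
#: (the bright GFAP-dense soma core) and puncta at ~1 μm. The soma scale is a
#: validity precondition of the synthetic world: somata must remain resolvable
#: at the clustered process's typical sibling spacing, as nucleus-guided
#: manual dot placement achieves on real tissue.
RENDER_DEFAULTS = dict(
    soma_sigma_um=2.5,
    punctum_sigma_um=0.75,
    amplitude=160.0,
    punctum_amplitude=120.0,
    background=10.0,
    noise_sd=4.0,
)


@dataclass(frozen=True)
class SceneSpec:
    """Generating parameters of one synthetic scene.

    Defaults describe a 0.4 mm² analysis frame (632 × 632 μm at 1 μm/px) with
    wild-type-like astrocyte abundance (~25 cells per frame), 35% dual-marker
    cells, an HD-model-like punctum load (~0.005/μm² in gray matter) reduced
    10-fold inside exclusion zones, and a handful of fascicles spanning the
    three size classes.
    """

    window_um: tuple[float, float] = (632.0, 632.0)
    pixel_size_um: float = 1.0
    seed: int = 0
    astro_process: str = "poisson"  # "poisson" | "thomas"
    intensity_lambda: float = 25 / (632.0 * 632.0)  # cells/μm² or parents/μm²
    offspring_mean: float = 5.0
    offspring_sigma_um: float = 10.0
    coloc_fraction: float = 0.35
    s100b_only_lambda: float = 25 / (632.0 * 632.0)
    puncta_density_in: float = 5e-4
    puncta_density_out: float = 5e-3
    fascicle_specs: tuple = (
        ((150.0, 150.0), (12.0, 10.0), 0.3),       # small, ~380 μm²
        ((450.0, 200.0), (35.0, 25.0), -0.5),      # medium, ~2,700 μm²
        ((280.0, 480.0), (55.0, 40.0), 1.0),       # large, ~6,900 μm²
    )
    exclusion: str = "both"  # puncta exclusion zones: "clusters"|"fascicles"|"both"|"none"
    cluster_zone_radius_um: float = 30.0
    render: dict = field(default_factory=lambda: dict(RENDER_DEFAULTS))

    def __post_init__(self) -> None:
        _check_window(self.window_um)
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError(f"coloc_fraction must be in [0,1], got {self.coloc_fraction}")
        for name in (
            "intensity_lambda",
            "offspring_mean",
            "offspring_sigma_um",
            "s100b_only_lambda",
            "puncta_density_in",
            "puncta_density_out",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.astro_process not in ("poisson", "thomas"):
            raise ValueError(f"unknown astro_process {self.astro_process!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        d["window_um"] = tuple(d["window_um"])
        d["fascicle_specs"] = tuple(
            (tuple(c), tuple(ax), th) for c, ax, th in d["fascicle_specs"]
        )
        return cls(**d)


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene: ground-truth points, masks and rendered channels."""

    spec: SceneSpec
    gfap: PointPattern
    gfap_parent_ids: np.ndarray        # empty for Poisson scenes
    gfap_parents: np.ndarray
    dual_flags: np.ndarray             # per-GFAP-cell: also S100B-positive
    s100b: PointPattern
    puncta: PointPattern
    fascicle_mask: np.ndarray
    exclusion_mask: np.ndarray
    channels: dict[str, np.ndarray]

    @property
    def ground_truth_clusters(self) -> dict[int, np.ndarray]:
        """Partition of GFAP cell indices by generating parent (Thomas only)."""
        out: dict[int, np.ndarray] = {}
        for j in np.unique(self.gfap_parent_ids):
            out[int(j)] = np.flatnonzero(self.gfap_parent_ids == j)
        return out


def wt_like_spec(seed: int = 0, **overrides) -> SceneSpec:
    """CSR astrocytes at baseline density — the wild-type-like stated world."""
    return SceneSpec(seed=seed, astro_process="poisson", **overrides)


def hd_like_spec(seed: int = 0, density_factor: float = 1.5, **overrides) -> SceneSpec:
    """Thomas-clustered astrocytes at ``density_factor`` × baseline density.

    Emulates the HD-model contrast: more cells, spatially clustered, puncta
    depleted inside cluster zones and fascicles.
    """
    base = SceneSpec.__dataclass_fields__["intensity_lambda"].default
    mu = overrides.pop("offspring_mean", 5.0)
    return SceneSpec(
        seed=seed,
        astro_process="thomas",
        intensity_lambda=density_factor * base / mu,
        offspring_mean=mu,
        **overrides,
    )


def build_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate the full scene described by *spec*, deterministically.

    All randomness flows from ``spec.seed`` through independent child
    generators (one per stochastic layer), so the same spec gives a
    bit-identical scene and layers do not perturb each other.
    """
    rng = np.random.default_rng(spec.seed)
    r_astro, r_dual, r_s100b, r_puncta, r_ch1, r_ch2, r_ch3 = rng.spawn(7)
    win, px = spec.window_um, spec.pixel_size_um

    if spec.astro_process == "poisson":
        gfap = simulate_poisson_pattern(spec.intensity_lambda, win, r_astro)
        parent_ids = np.empty(0, dtype=int)
        parents = np.empty((0, 2))
    else:
        gfap, parent_ids, parents = simulate_thomas_pattern(
            spec.intensity_lambda,
            spec.offspring_mean,
            spec.offspring_sigma_um,
            win,
            r_astro,
        )

    dual = r_dual.random(gfap.n) < spec.coloc_fraction
    s100b_only = simulate_poisson_pattern(spec.s100b_only_lambda, win, r_s100b)
    s100b_pts = (
        np.concatenate([gfap.points[dual], s100b_only.points])
        if gfap.n or s100b_only.n
        else np.empty((0, 2))
    )
    s100b = PointPattern(s100b_pts, win)

    fascicle_mask = fascicle_mask_from_specs(list(spec.fascicle_specs), win, px)
    exclusion = np.zeros_like(fascicle_mask)
    if spec.exclusion in ("fascicles", "both"):
        exclusion |= fascicle_mask
    if spec.exclusion in ("clusters", "both") and len(parents):
        ny, nx = exclusion.shape
        yy = (np.arange(ny)[:, None] + 0.5) * px
        xx = (np.arange(nx)[None, :] + 0.5) * px
        # zones only around parents that actually emitted ≥2 cells
        counts = np.bincount(parent_ids, minlength=len(parents))
        for j, p in enumerate(parents):
            if counts[j] < 2:
                continue
            exclusion |= (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= spec.cluster_zone_radius_um**2

    puncta = generate_puncta_field(
        spec.puncta_density_in,
        spec.puncta_density_out,
        exclusion,
        win,
        px,
        r_puncta,
    )

    rd = spec.render
    channels = {
        "gfap": render_channel(
            gfap, rd["soma_sigma_um"], rd["amplitude"], rd["background"],
            rd["noise_sd"], px, r_ch1,
        ),
        "s100b": render_channel(
            s100b, rd["soma_sigma_um"], rd["amplitude"], rd["background"],
            rd["noise_sd"], px, r_ch2,
        ),
        "puncta": render_channel(
            puncta, rd["punctum_sigma_um"], rd["punctum_amplitude"],
            rd["background"], rd["noise_sd"], px, r_ch3,
        ),
    }
    return SyntheticScene(
        spec=spec,
        gfap=gfap,
        gfap_parent_ids=parent_ids,
        gfap_parents=parents,
        dual_flags=dual,
        s100b=s100b,
        puncta=puncta,
        fascicle_mask=fascicle_mask,
        exclusion_mask=exclusion,
        channels=channels,
    )


# -- scene I/O -------------------------------------------------------------

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write a scene to disk: channels as multi-page TIFF, ground truth as CSV,
    masks as single-page TIFFs, the spec as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = sorted(scene.channels)
    tifffile.imwrite(
        out / "channels.tif",
        np.stack([scene.channels[k] for k in names]),
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": names},
    )
    tifffile.imwrite(out / "fascicle_mask.tif", scene.fascicle_mask.astype(np.uint8))
    tifffile.imwrite(out / "exclusion_mask.tif", scene.exclusion_mask.astype(np.uint8))
    rows = []
    for i, (x, y) in enumerate(scene.gfap.points):
        pid = int(scene.gfap_parent_ids[i]) if len(scene.gfap_parent_ids) else -1
        rows.append((x, y, "gfap", pid))
        if scene.dual_flags[i]:
            rows.append((x, y, "s100b", pid))
    n_dual = int(scene.dual_flags.sum())
    for x, y in scene.s100b.points[n_dual:]:
        rows.append((x, y, "s100b", -1))
    for x, y in scene.puncta.points:
        rows.append((x, y, "puncta", -1))
    pd.DataFrame(rows, columns=["x_um", "y_um", "marker", "parent_id"]).to_csv(
        out / "ground_truth.csv", index=False
    )
    (out / "spec.json").write_text(scene.spec.to_json())
    return out


def read_scene_spec(path: str | Path) -> SceneSpec:
    return SceneSpec.from_json(Path(path).read_text())
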