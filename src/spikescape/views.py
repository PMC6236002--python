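"""Offline renderers for the four activity views.

* view 1 — per-population image plots of the instantaneous spike-count rate,
  with a shared black-red-yellow-white lookup table,
* view 2 — cube-glyph layouts whose volumes are proportional to the bin rate,
  plus per-axis marginal projections,
* view 3 — the total spike-count rate series with per-population stacked
  fractions,
* view 4 — rate iso-surfaces of the (x, y, lag) volume extracted by marching
  cubes,
* raw variants — per-spike markers at unit positions at native resolution.

The renderers return plain geometry/array objects; thin export helpers write
PNG/SVG images and Wavefront OBJ meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedRates, total_rate_series

__all__ = [
    "FrameImage",
    "CubeLayout",
    "RateSeries",
    "IsoSurfaceMesh",
    "colormap",
    "view1_frame",
    "view2_layout",
    "view3_series",
    "view4_isosurface",
    "raw_frame",
    "save_frame_png",
    "save_frame_svg",
    "save_series_plot",
    "save_layout_plot",
    "write_obj",
]

POPULATION_COLORS = {"EX": "#3465a4", "IN": "#cc0000", "STIM": "#888a85"}


def colormap() -> np.ndarray:
    """256-entry black->red->yellow->white lookup table, uint8 RGB.

    Piecewise-linear between the four anchors; lightness increases
    monotonically along the table (approximately perceptually uniform).
    """
    anchors = np.array([[0, 0, 0], [255, 0, 0], [255, 255, 0], [255, 255, 255]],
                       dtype=np.float64)
    pos = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    x = np.linspace(0.0, 1.0, 256)
    rgb = np.stack([np.interp(x, pos, anchors[:, c]) for c in range(3)], axis=1)
    return np.rint(rgb).astype(np.uint8)


@dataclass
class FrameImage:
    """One population's rate slice at temporal bin k."""

    population: str
    k: int
    values: np.ndarray   # (Lx, Ly) spikes/s, index (lx, ly)
    vmax: float          # shared color range across populations

    def lookup_indices(self) -> np.ndarray:
        if self.vmax <= 0:
            return np.zeros(self.values.shape, dtype=np.intp)
        return np.clip(
            np.floor(self.values / self.vmax * 255).astype(np.intp), 0, 255
        )

    def to_rgb(self) -> np.ndarray:
        """(rows, cols, 3) uint8 image; x rightward, y upward."""
        lut = colormap()
        idx = self.lookup_indices()
        return lut[idx.T[::-1]]  # row 0 = top = largest ly


def view1_frame(binned: BinnedRates, k: int, vmax: float | None = None) -> FrameImage:
    """Image-plot slice of one population at temporal bin ``k``.

    ``vmax`` should be the maximum over all populations (and, by default
    choice, over the whole record) so the color scale is shared.
    """
    if not 0 <= k < binned.shape[2]:
        raise IndexError(f"temporal bin {k} outside [0, {binned.shape[2]})")
    values = binned.rates[:, :, k]
    if vmax is None:
        vmax = float(binned.rates.max())
    return FrameImage(binned.population, k, values.copy(), vmax)


@dataclass
class CubeLayout:
    """Cube glyphs of one frame: centers (mm), edges (mm), colors, opacity."""

    k: int
    centers: dict = field(default_factory=dict)    # pop -> (n, 2) bin centers
    edges: dict = field(default_factory=dict)      # pop -> (n,) edge lengths
    values: dict = field(default_factory=dict)     # pop -> (n,) rates
    projections: dict = field(default_factory=dict)  # pop -> (x_prof, y_prof)
    colors: dict = field(default_factory=dict)
    opacity: float = 1.0


def view2_layout(binned: dict, k: int, scale_mode: str = "volume") -> CubeLayout:
    """Cube-glyph layout for all populations at temporal bin ``k``.

    Default scaling makes the cube volume proportional to the bin rate
    (edge ~ rate^(1/3)); ``scale_mode="linear"`` scales the side length
    linearly instead.  The maximum edge equals the bin width.  Marginal sums
    along each spatial axis are emitted as per-population 1D profiles.
    """
    layout = CubeLayout(k=k)
    vmax = max((float(g.rates.max()) for g in binned.values()), default=0.0)
    for label, g in binned.items():
        if not 0 <= k < g.shape[2]:
            raise IndexError(f"temporal bin {k} outside [0, {g.shape[2]})")
        sl = g.rates[:, :, k]
        lx, ly = np.nonzero(sl)
        vals = sl[lx, ly]
        cx = (lx + 0.5) * g.dl_bin - g.L / 2
        cy = (ly + 0.5) * g.dl_bin - g.L / 2
        if vmax > 0:
            rel = vals / vmax
            edges = g.dl_bin * (np.cbrt(rel) if scale_mode == "volume" else rel)
        else:
            edges = np.zeros_like(vals)
        layout.centers[label] = np.column_stack([cx, cy])
        layout.edges[label] = edges
        layout.values[label] = vals
        layout.projections[label] = (sl.sum(axis=1), sl.sum(axis=0))
        layout.colors[label] = POPULATION_COLORS.get(label, "#000000")
    return layout


@dataclass
class RateSeries:
    """View-3 payload: total rate line plus stacked population fractions."""

    k_indices: np.ndarray
    nu_k: np.ndarray
    fractions: dict        # pop -> array over k_indices (hidden pops omitted)
    cumulative: dict       # pop -> stacked upper edge
    k_center: int


def view3_series(binned: dict, k_center: int, half_window: int,
                 hidden=()) -> RateSeries:
    """Windowed total-rate series centered on the current step.

    The window is clipped at the record edges.  ``hidden`` populations are
    left out of the stacked fractions only; the total ``nu_k`` always sums
    over all populations.
    """
    nu_k, fractions = total_rate_series(binned)
    K = len(nu_k)
    lo = max(0, k_center - half_window)
    hi = min(K, k_center + half_window + 1)
    sel = np.arange(lo, hi)
    shown = {p: f[sel] for p, f in fractions.items() if p not in set(hidden)}
    cumulative = {}
    running = np.zeros(len(sel))
    for p, f in shown.items():
        running = running + f
        cumulative[p] = running.copy()
    return RateSeries(
        k_indices=sel, nu_k=nu_k[sel], fractions=shown,
        cumulative=cumulative, k_center=k_center,
    )


@dataclass
class IsoSurfaceMesh:
    """Triangulated rate iso-surface in physical coordinates."""

    population: str
    iso_value: float
    vertices: np.ndarray   # (n, 3): x mm, y mm, lag ms
    faces: np.ndarray      # (m, 3) vertex indices

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0


def view4_isosurface(binned: BinnedRates, k_center: int, half_window: int,
                     iso_value: float, temporal_offset: float = 0.0
                     ) -> IsoSurfaceMesh:
    """Marching-cubes surface of the (x, y, lag) rate volume at ``iso_value``.

    Vertices are interpolated along cell edges and scaled to physical units;
    lags are relative to ``k_center`` (plus an optional per-population
    offset).  A threshold above the volume maximum yields an empty mesh.
    """
    from skimage.measure import marching_cubes

    if iso_value <= 0:
        raise ValueError("iso_value must be > 0")
    K = binned.shape[2]
    lo = max(0, k_center - half_window)
    hi = min(K, k_center + half_window + 1)
    if hi <= lo:
        raise ValueError("empty time window")
    volume = binned.rates[:, :, lo:hi].astype(np.float64).copy()
    # nudge exact threshold hits to avoid degenerate zero-length edges; the
    # offset must survive the float32 cast inside the extraction routine
    ties = volume == iso_value
    if ties.any():
        volume[ties] += 1e-5 * iso_value
    if volume.max() < iso_value or volume.min() > iso_value:
        return IsoSurfaceMesh(binned.population, iso_value,
                              np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))
    verts, faces, _, _ = marching_cubes(
        volume, level=iso_value,
        spacing=(binned.dl_bin, binned.dl_bin, binned.dt_bin),
    )
    verts = verts.copy()
    verts[:, 0] += binned.dl_bin / 2 - binned.L / 2
    verts[:, 1] += binned.dl_bin / 2 - binned.L / 2
    verts[:, 2] += (lo - k_center) * binned.dt_bin + temporal_offset
    return IsoSurfaceMesh(binned.population, iso_value, verts,
                          faces.astype(np.int64))


def enclosed_volume(binned: BinnedRates, iso_value: float,
                    k_center: int, half_window: int) -> float:
    """Voxel-count estimate (mm^2*ms) of the super-threshold region."""
    K = binned.shape[2]
    lo = max(0, k_center - half_window)
    hi = min(K, k_center + half_window + 1)
    vol = binned.rates[:, :, lo:hi]
    return float((vol >= iso_value).sum()) * binned.dl_bin ** 2 * binned.dt_bin


def raw_frame(ids, times, pos_ids, x, y, population: str, k: int, dt: float,
              dilution: int = 1):
    """Marker list of view 1/2 raw mode: one square per spike in step ``k``.

    ``dilution`` keeps only every n-th unit in ID order (a dilution of 5
    shows the spikes of every fifth unit).
    """
    ids = np.asarray(ids, dtype=np.int64)
    times = np.asarray(times, dtype=np.float64)
    pos_ids = np.asarray(pos_ids, dtype=np.int64)
    # epsilon guards against grid times like 0.3/0.1 flooring one step low
    in_step = np.floor(times / dt + 1e-7).astype(np.int64) == k
    sel_ids = ids[in_step]
    if dilution > 1:
        uniq = np.sort(np.unique(pos_ids))
        kept = set(uniq[::dilution].tolist())
        keep = np.array([i in kept for i in sel_ids], dtype=bool) \
            if sel_ids.size else np.empty(0, bool)
        sel_ids = sel_ids[keep]
    order = np.argsort(pos_ids)
    loc = order[np.searchsorted(pos_ids[order], sel_ids)] \
        if sel_ids.size else np.empty(0, np.intp)
    return {
        "population": population,
        "color": POPULATION_COLORS.get(population, "#000000"),
        "x": np.asarray(x)[loc],
        "y": np.asarray(y)[loc],
        "ids": sel_ids,
    }


# ---------------------------------------------------------------------------
# export helpers


def save_frame_png(frame: FrameImage, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, frame.to_rgb())


def save_frame_svg(frame: FrameImage, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = ListedColormap(colormap() / 255.0)
    ax.imshow(frame.values.T[::-1], cmap=cmap, vmin=0,
              vmax=frame.vmax if frame.vmax > 0 else 1.0)
    ax.set_title(f"{frame.population}, k={frame.k}")
    ax.set_xlabel("lx")
    ax.set_ylabel("ly")
    fig.savefig(path, format="svg")
    plt.close(fig)


def save_series_plot(series: RateSeries, dt_bin: float, path) -> None:
    """Stacked-fraction plot with the total-rate line on top (PNG or SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 4))
    t = series.k_indices * dt_bin
    ax1.plot(t, series.nu_k, color="black", lw=1)
    ax1.set_ylabel(r"$\nu_k$ (spikes/s)")
    lower = np.zeros(len(t))
    for pop, upper in series.cumulative.items():
        ax2.fill_between(t, lower, upper, label=pop,
                         color=POPULATION_COLORS.get(pop, None))
        lower = upper
    ax2.axvline(series.k_center * dt_bin, color="white", lw=1)
    ax2.set_xlabel("time (ms)")
    ax2.set_ylabel("fraction")
    ax2.legend(loc="upper right", fontsize=7)
    fig.savefig(path)
    plt.close(fig)


def save_layout_plot(layout: CubeLayout, L: float, path, lfp_image=None) -> None:
    """Top-down rendering of the cube layout (glyph area ~ edge^2)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if lfp_image is not None:
        ax.imshow(lfp_image.T[::-1], extent=[-L / 2, L / 2, -L / 2, L / 2],
                  cmap="PRGn", alpha=0.6)
    for pop, centers in layout.centers.items():
        if len(centers) == 0:
            continue
        sizes = (layout.edges[pop] / L * 72 * 5) ** 2
        ax.scatter(centers[:, 0], centers[:, 1], s=sizes, marker="s",
                   color=layout.colors[pop], alpha=layout.opacity, label=pop)
    ax.set_xlim(-L / 2, L / 2)
    ax.set_ylim(-L / 2, L / 2)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path)
    plt.close(fig)


def write_obj(mesh: IsoSurfaceMesh, path) -> None:
    """Wavefront OBJ export of an iso-surface mesh."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(f"o {mesh.population}_iso{mesh.iso_value:g}\n")
        for vx, vy, vz in mesh.vertices:
            fh.write(f"v {vx:.6f} {vy:.6f} {vz:.6f}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")
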