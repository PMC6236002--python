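"""Readers and writers for the plain-text exchange formats.

Four formats are shared across the package:

* raw spikes: two space-separated columns ``ID time_ms`` (times on the ``dt``
  grid, one decimal); a dialect with integer step numbers instead of times is
  accepted on read,
* positions: three columns ``ID x_mm y_mm``,
* binned spike rates: four columns ``lx ly k rate`` with zero-rate rows
  omitted,
* binned analog values (e.g. LFP in mV): same four columns, but zero rows are
  retained because zero is informative for a signed signal.

Writers emit exactly one dialect (ASCII, ``\\n`` newlines, no trailing
whitespace); readers are tolerant: they accept permuted row order for binned
data and report malformed lines with their line number.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_positions",
    "write_positions",
    "read_binned",
    "write_binned",
]


class ParseError(ValueError):
    pass


def _parse_columns(path, n_cols, kinds):
    cols = [[] for _ in range(n_cols)]
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            try:
                for col, kind, tok in zip(cols, kinds, parts):
                    col.append(kind(tok))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return cols


def read_spikes(path, steps_dt: float | None = None):
    """Read a two-column spike file.

    Parameters
    ----------
    path:
        File with rows ``ID time``.
    steps_dt:
        If given, the second column is interpreted as integer grid-step
        numbers ``n`` and converted to milliseconds as ``n * steps_dt``.

    Returns
    -------
    (ids, times):
        ``int64`` neuron IDs and ``float64`` spike times in ms.
    """
    ids, times = _parse_columns(path, 2, (int, float))
    ids = np.asarray(ids, dtype=np.int64)
    times = np.asarray(times, dtype=np.float64)
    if steps_dt is not None:
        if not np.all(times == np.rint(times)):
            raise ParseError(f"{path}: step dialect requires integer time entries")
        times = times * steps_dt
    return ids, times


def write_spikes(path, ids, times) -> None:
    ids = np.asarray(ids)
    times = np.asarray(times)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for i, t in zip(ids, times):
            fh.write(f"{int(i)} {t:.1f}\n")


def read_positions(path):
    """Read ``ID x y`` rows; coordinates in mm."""
    ids, x, y = _parse_columns(path, 3, (int, float, float))
    return (
        np.asarray(ids, dtype=np.int64),
        np.asarray(x, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
    )


def write_positions(path, ids, x, y) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for i, xi, yi in zip(ids, x, y):
            fh.write(f"{int(i)} {xi:.6f} {yi:.6f}\n")


def read_binned(path, Lx: int, Ly: int, K: int, analog: bool = False):
    """Read a four-column binned file into a dense ``(Lx, Ly, K)`` grid.

    The reader keys rows by their ``(lx, ly, k)`` indices and therefore
    accepts any row ordering.  Missing rows are zeros.
    """
    lx, ly, k, val = _parse_columns(path, 4, (int, int, int, float))
    lx = np.asarray(lx, dtype=np.intp)
    ly = np.asarray(ly, dtype=np.intp)
    k = np.asarray(k, dtype=np.intp)
    val = np.asarray(val, dtype=np.float64)
    for name, idx, n in (("lx", lx, Lx), ("ly", ly, Ly), ("k", k, K)):
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ParseError(f"{path}: {name} index out of range [0, {n})")
    grid = np.zeros((Lx, Ly, K), dtype=np.float64)
    grid[lx, ly, k] = val
    return grid


def write_binned(path, grid, analog: bool = False) -> None:
    """Write a dense grid as ``lx ly k value`` rows.

    Spike-rate grids omit zero rows; analog grids retain them.  Rows iterate
    with ``k`` fastest, then ``lx``, then ``ly``.
    """
    grid = np.asarray(grid)
    Lx, Ly, K = grid.shape
    fmt = "{} {} {} {:.6e}\n" if analog else "{} {} {} {:g}\n"
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for ly in range(Ly):
            for lx in range(Lx):
                row = grid[lx, ly]
                for k in range(K):
                    v = row[k]
                    if analog or v != 0.0:
                        fh.write(fmt.format(lx, ly, k, v))
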