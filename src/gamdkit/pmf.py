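"""Potential-of-mean-force container shared by the oracle and reweighting code.

A :class:`PMF` holds a binned free-energy profile over one or two collective
variables, together with the per-bin quantities the cumulant-expansion
reweighting produces (counts, first two cumulants of the boost potential,
biased and reweighted probabilities).  Free energies are in units of k_B T and
min-shifted so the global minimum is zero; bins with fewer than the requested
minimum number of samples are masked and carry ``nan`` free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PMF:
    """Binned (reweighted) free-energy surface over 1 or 2 collective variables."""

    dimensionality: int
    bin_edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray          # k_B T, min-shifted to 0, nan on masked bins
    reweighted_probability: np.ndarray   # sums to 1 over unmasked bins
    biased_probability: np.ndarray       # p*(A), sums to 1 over all bins
    counts: np.ndarray | None = None     # per-bin frame counts (None for exact oracles)
    c1: np.ndarray | None = None         # per-bin mean of the boost potential
    c2: np.ndarray | None = None         # per-bin population variance of the boost
    mask: np.ndarray | None = None       # True where the bin has enough samples
    temperature: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = tuple(np.asarray(e, dtype=float) for e in self.bin_edges)
        if len(self.bin_edges) != self.dimensionality:
            raise ValueError("one edge array per dimension is required")
        shape = tuple(len(e) - 1 for e in self.bin_edges)
        if self.free_energy.shape != shape:
            raise ValueError(
                f"free_energy shape {self.free_energy.shape} does not match bins {shape}"
            )
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.bin_edges)

    def centers(self, dim: int = 0) -> np.ndarray:
        e = self.bin_edges[dim]
        return 0.5 * (e[:-1] + e[1:])

    # -- convenience ------------------------------------------------------
    def minimum_location(self) -> tuple[float, ...]:
        """Coordinates (bin centers) of the global free-energy minimum."""
        idx = np.unravel_index(np.nanargmin(self.free_energy), self.shape)
        return tuple(self.centers(d)[i] for d, i in enumerate(idx))

    def value_at(self, *coords: float) -> float:
        """Free energy of the bin containing the given CV coordinates."""
        idx = []
        for d, c in enumerate(coords):
            i = int(np.digitize(c, self.bin_edges[d]) - 1)
            if not 0 <= i < self.shape[d]:
                raise ValueError(f"coordinate {c} outside the binned range in dim {d}")
            idx.append(i)
        return float(self.free_energy[tuple(idx)])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: bin centers, counts, cumulants and free energy."""
        grids = np.meshgrid(*[self.centers(d) for d in range(self.dimensionality)],
                            indexing="ij")
        data = {f"cv{d + 1}": g.ravel() for d, g in enumerate(grids)}
        if self.counts is not None:
            data["count"] = self.counts.ravel()
        if self.c1 is not None:
            data["c1"] = self.c1.ravel()
        if self.c2 is not None:
            data["c2"] = self.c2.ravel()
        data["p_biased"] = self.biased_probability.ravel()
        data["p_reweighted"] = self.reweighted_probability.ravel()
        data["free_energy"] = self.free_energy.ravel()
        return pd.DataFrame(data)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None, ceiling: float = 8.0):
        """Quick-look plot; 2D surfaces use a green-white-red scale capped at
        ``ceiling`` k_B T (masked bins blank)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.dimensionality == 1:
            ax.plot(self.centers(0), self.free_energy, marker=".")
            ax.set_xlabel("collective variable")
            ax.set_ylabel("free energy (k$_B$T)")
        else:
            f = np.where(self.mask, np.minimum(self.free_energy, ceiling), np.nan)
            im = ax.pcolormesh(self.bin_edges[0], self.bin_edges[1], f.T,
                               cmap="PiYG_r", vmin=0.0, vmax=ceiling)
            ax.figure.colorbar(im, ax=ax, label="free energy (k$_B$T)")
            ax.set_xlabel("cv1")
            ax.set_ylabel("cv2")
        if self.label:
            ax.set_title(self.label)
        return ax


def local_minima(pmf: PMF, depth_cutoff: float = 2.0) -> list[tuple[float, ...]]:
    """Locate local minima of a PMF below ``depth_cutoff`` k_B T.

    A bin is a local minimum when its free energy is finite, below the cutoff
    and not larger than any of its (axis-aligned and diagonal) neighbours.
    Returns bin-center coordinates sorted by free energy.
    """
    f = np.where(pmf.mask, pmf.free_energy, np.inf)
    f = np.nan_to_num(f, nan=np.inf)
    shape = f.shape
    minima: list[tuple[float, float]] = []
    it = np.ndindex(*shape)
    for idx in it:
        v = f[idx]
        if not np.isfinite(v) or v > depth_cutoff:
            continue
        is_min = True
        for offset in np.ndindex(*(3,) * len(shape)):
            d = tuple(o - 1 for o in offset)
            if all(o == 0 for o in d):
                continue
            nidx = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nidx, shape)):
                if f[nidx] < v:
                    is_min = False
                    break
        if is_min:
            coords = tuple(pmf.centers(d)[i] for d, i in enumerate(idx))
            minima.append((v, coords))
    minima.sort(key=lambda t: t[0])
    return [c for _, c in minima]
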