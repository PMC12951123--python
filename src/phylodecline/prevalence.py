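"""Environmental prevalence: the relative geographic availability of climate.

A climate layer is binned into 60 equal-width intervals over a fixed support
(annual mean temperature: -27 to 31 degC; climate moisture index: -312 to 390
kg m^-2 month^-1) and the prevalence of each bin is the fraction of valid land
cells falling in it. The rare extreme bin (coldest for temperature, wettest
for moisture) is lumped into its neighbor. A species' prevalence is the
prevalence of the bin whose center is nearest its range-mean climate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_BINS = 60
SUPPORTS = {
    "amt": (-27.0, 31.0),
    "cmi": (-312.0, 390.0),
}
#: which extreme bin is rare enough to merge into its neighbor
LUMP_SIDE = {"amt": "low", "cmi": "high"}


def build_bins(variable: str) -> np.ndarray:
    """61 equally spaced edges spanning the variable's fixed support."""
    try:
        lo, hi = SUPPORTS[variable]
    except KeyError:
        raise ValueError(f"unknown variable {variable!r}; expected amt or cmi")
    return np.linspace(lo, hi, N_BINS + 1)


@dataclass
class PrevalenceProfile:
    """Per-bin fraction of valid land cells, after lumping."""

    variable: str
    bin_edges: np.ndarray          # post-lumping edges, len = n_bins + 1
    prevalence: np.ndarray         # post-lumping fractions, sum to 1
    lumped_bins: list = field(default_factory=list)  # [(absorbed, into)]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable": self.variable,
                "bin_edges": [float(v) for v in self.bin_edges],
                "prevalence": [float(v) for v in self.prevalence],
                "lumped_bins": self.lumped_bins,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PrevalenceProfile":
        d = json.loads(text)
        return cls(
            variable=d["variable"],
            bin_edges=np.array(d["bin_edges"], dtype=float),
            prevalence=np.array(d["prevalence"], dtype=float),
            lumped_bins=[tuple(p) for p in d["lumped_bins"]],
        )


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi), last closed; out-of-range clamped to extremes."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def prevalence_distribution(
    layer: np.ndarray,
    mask: np.ndarray | None,
    edges: np.ndarray,
    lump: str | None = None,
) -> PrevalenceProfile:
    """Fraction of valid cells per bin, with the designated extreme bin lumped.

    ``mask`` is a boolean validity mask (True = use the cell); NaN cells are
    always skipped. ``lump`` is ``"low"``, ``"high"``, or None; with lumping,
    the extreme bin's mass is merged into its adjacent neighbor and the merged
    edge removed.
    """
    values = np.asarray(layer, dtype=float).ravel()
    valid = np.isfinite(values)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool).ravel()
    values = values[valid]
    if values.size == 0:
        raise ValueError("all cells masked; prevalence undefined")
    idx = _bin_index(values, edges)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    prev = counts / counts.sum()

    edges = np.asarray(edges, dtype=float).copy()
    lumped: list[tuple[int, int]] = []
    if lump == "low":
        prev[1] += prev[0]
        prev = prev[1:]
        edges = np.delete(edges, 1)
        lumped.append((0, 1))
    elif lump == "high":
        prev[-2] += prev[-1]
        prev = prev[:-1]
        edges = np.delete(edges, len(edges) - 2)
        lumped.append((len(prev), len(prev) - 1))
    elif lump is not None:
        raise ValueError(f"lump must be 'low', 'high' or None, got {lump!r}")
    return PrevalenceProfile("custom", edges, prev, lumped)


def climate_prevalence(layer: np.ndarray, mask: np.ndarray | None,
                       variable: str) -> PrevalenceProfile:
    """Standard profile for a named variable: fixed bins + its lumping rule."""
    profile = prevalence_distribution(
        layer, mask, build_bins(variable), lump=LUMP_SIDE[variable]
    )
    profile.variable = variable
    return profile


def species_prevalence(species_mean: float, profile: PrevalenceProfile) -> float:
    """Prevalence of the (post-lumping) bin nearest the species' mean climate.

    Ties between bin centers resolve toward the lower bin; a missing mean
    propagates as NaN.
    """
    if species_mean is None or not np.isfinite(species_mean):
        return float("nan")
    centers = profile.bin_centers
    dist = np.abs(centers - species_mean)
    return float(profile.prevalence[int(np.argmin(dist))])


def species_prevalence_from_cells(cell_values, profile: PrevalenceProfile) -> float:
    """Range-overlap-weighted species prevalence (non-default variant).

    Instead of the single bin nearest the range mean, averages the prevalence
    of the bin containing each of the species' cell values, weighting bins by
    how much of the range falls in them. NaN cells are skipped; an empty or
    all-NaN range is missing.
    """
    values = np.asarray(cell_values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    idx = _bin_index(values, profile.bin_edges)
    return float(np.mean(profile.prevalence[idx]))
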