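"""The three PM display families.

* Trellis curve grids: the 96 wells arranged in the original 8x12 plate
  layout, one panel per well, replicate/strain curves superimposed and
  color-coded -- the workhorse view for eyeballing data quality.
* Level maps: every curve as a thin horizontal strip whose color intensity
  encodes signal height; hundreds of curves fit on one page, and
  non-monotone stretches stand out as darker-to-lighter reversals.
* CI dot-whisker panels: one panel per parameter (lambda, mu, A, AUC),
  point estimate plus interval per curve or group, optional reference
  lines at a highlighted curve's limits, and difference-of-means panels
  drawn against a zero line.

Every function returns a :class:`PlotResult` whose ``layers`` attribute
exposes exactly what was drawn (labels, coordinates, colors), so tests and
callers can assert on the data layer instead of pixels.  Plotting is a
pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .core import PARAMETER_NAMES, ParameterCI, Plate, WellCoordinate
from .uncertainty import GroupComparison

__all__ = ["PlotResult", "plot_plate_grid", "plot_levelmap", "plot_parameter_cis"]

_DEFAULT_CYCLE = ("black", "red", "green", "blue", "purple", "orange", "teal", "brown")


@dataclass
class PlotResult:
    """A rendered figure plus its inspectable data layer."""

    figure: plt.Figure
    layers: dict

    def save(self, path, format: Optional[str] = None, dpi: int = 150) -> None:
        self.figure.savefig(path, format=format, dpi=dpi, bbox_inches="tight")

    def close(self) -> None:
        plt.close(self.figure)


def _group_colors(groups: Sequence[str], colors: Optional[Mapping[str, str]]) -> Dict[str, str]:
    if colors is None:
        return {g: _DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i, g in enumerate(groups)}
    missing = [g for g in groups if g not in colors]
    if missing:
        raise ValueError(f"color map lacks groups: {missing}")
    if len(set(colors[g] for g in groups)) < len(groups):
        raise ValueError("color map must be injective over groups")
    return {g: colors[g] for g in groups}


def plot_plate_grid(
    plates: Union[Plate, Sequence[Plate]],
    wells: Optional[Sequence[str]] = None,
    group_by: str = "strain",
    colors: Optional[Mapping[str, str]] = None,
    substrate_names: Optional[Mapping[str, str]] = None,
    path=None,
) -> PlotResult:
    """Superimposed curves per well, arranged in the 8x12 plate layout.

    One panel per requested well (all 96 by default, or a subset);
    within each panel one curve per plate, colored by the grouping
    variable (strain by default).  Panel captions carry the well
    coordinate, optionally followed by the substrate name.
    """
    if isinstance(plates, Plate):
        plates = [plates]
    if not plates:
        raise ValueError("need at least one plate")
    if wells is None:
        seen = sorted({label for p in plates for label in p.curves})
        wells = seen
    else:
        wells = [WellCoordinate.from_label(w).label for w in wells]

    groups: List[str] = []
    for p in plates:
        for label in wells:
            if label in p.curves:
                g = getattr(p.curves[label], group_by, None) or (p.plate_id or "plate")
                if g not in groups:
                    groups.append(g)
    color_map = _group_colors(groups, colors)

    if len(wells) == 96:
        nrows, ncols = 8, 12
    else:
        ncols = min(len(wells), 12)
        nrows = int(np.ceil(len(wells) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(1.6 * ncols, 1.3 * nrows), squeeze=False,
        sharex=True, sharey=True,
    )
    layers: Dict[str, list] = {}
    for i, label in enumerate(wells):
        ax = axes[i // ncols][i % ncols]
        caption = label
        if substrate_names and label in substrate_names:
            caption = f"{label} {substrate_names[label]}"
        ax.set_title(caption, fontsize=6)
        panel = []
        for p in plates:
            if label not in p.curves:
                continue
            curve = p.curves[label]
            g = getattr(curve, group_by, None) or (p.plate_id or "plate")
            ax.plot(curve.times, curve.values, color=color_map[g], linewidth=0.6)
            panel.append(
                {"group": g, "color": color_map[g],
                 "times": curve.times, "values": curve.values}
            )
        layers[label] = panel
    for j in range(len(wells), nrows * ncols):
        axes[j // ncols][j % ncols].set_axis_off()
    result = PlotResult(fig, {"panels": layers, "colors": color_map})
    if path is not None:
        result.save(path)
    return result


def plot_levelmap(
    plates: Union[Plate, Sequence[Plate]],
    order: Optional[Sequence[str]] = None,
    cmap: str = "viridis",
    path=None,
) -> PlotResult:
    """Stacked heat strips, one per well: x = time, intensity = signal.

    ``order`` is a sequence of strip keys ``"plate_id/well"`` (or plain
    well labels for a single plate) defining the display order top to
    bottom; by default strips follow plate order.
    """
    if isinstance(plates, Plate):
        plates = [plates]
    strips = {}
    for p in plates:
        for label in sorted(p.curves):
            key = f"{p.plate_id}/{label}" if p.plate_id else label
            strips[key] = p.curves[label]
    if order is None:
        keys = list(strips)
    else:
        keys = []
        for k in order:
            if k in strips:
                keys.append(k)
            else:
                matches = [s for s in strips if s.endswith("/" + k) or s == k]
                if len(matches) != 1:
                    raise KeyError(f"strip key {k!r} not found or ambiguous")
                keys.append(matches[0])

    times = strips[keys[0]].times
    matrix = np.vstack([strips[k].values for k in keys])
    fig, ax = plt.subplots(figsize=(8, max(2, 0.05 * len(keys))))
    ax.pcolormesh(times, np.arange(len(keys)), matrix, cmap=cmap, shading="nearest")
    ax.set_xlabel("time [h]")
    ax.invert_yaxis()
    result = PlotResult(fig, {"order": keys, "matrix": matrix, "times": times})
    if path is not None:
        result.save(path)
    return result


def plot_parameter_cis(
    ci_sets: Mapping[str, Mapping[str, ParameterCI]],
    reference: Optional[str] = None,
    differences: Optional[GroupComparison] = None,
    path=None,
) -> PlotResult:
    """Dot-whisker panels of the four parameters, optional difference panels.

    ``ci_sets`` maps a curve/group id to its per-parameter intervals.  The
    ``reference`` id's limits are drawn as vertical lines across its
    panel.  With ``differences``, a second row shows the simultaneous
    intervals for group-mean differences against a zero line: an interval
    clear of zero flags a statistically detectable difference.
    """
    ids = list(ci_sets)
    if not ids:
        raise ValueError("no CI sets given")
    levels = {ci.level for cis in ci_sets.values() for ci in cis.values()}
    if len(levels) > 1:
        raise ValueError(f"mixed CI levels: {sorted(levels)}")
    if reference is not None and reference not in ci_sets:
        raise KeyError(f"reference id {reference!r} not among the CI sets")

    nrows = 2 if differences is not None else 1
    fig, axes = plt.subplots(nrows, 4, figsize=(14, 3.2 * nrows), squeeze=False)
    layers: Dict[str, dict] = {"whiskers": {}, "reference": {}, "differences": {}}
    for col, name in enumerate(PARAMETER_NAMES):
        ax = axes[0][col]
        ax.set_title(name)
        entries = []
        for row, ident in enumerate(ids):
            ci = ci_sets[ident].get(name)
            if ci is None:
                continue
            ax.errorbar(
                ci.point, row,
                xerr=[[ci.point - ci.lower], [ci.upper - ci.point]],
                fmt="o", markersize=3, capsize=2, color="black",
            )
            entries.append({"id": ident, "point": ci.point,
                            "lower": ci.lower, "upper": ci.upper})
        ax.set_yticks(range(len(ids)))
        ax.set_yticklabels(ids, fontsize=6)
        layers["whiskers"][name] = entries
        if reference is not None and name in ci_sets[reference]:
            ref = ci_sets[reference][name]
            ax.axvline(ref.lower, color="blue", linewidth=0.8)
            ax.axvline(ref.upper, color="blue", linewidth=0.8)
            layers["reference"][name] = {"lower": ref.lower, "upper": ref.upper}

    if differences is not None:
        names = [
            " - ".join(
                f"{c:+g}*{g}" for c, g in zip(row, differences.groups) if c
            )
            for row in differences.contrasts
        ]
        for col in range(4):
            ax = axes[1][col]
            if col > 0:
                ax.set_axis_off()
                continue
            ax.axvline(0.0, color="gray", linewidth=0.8)
            entries = []
            for row, (est, lo, hi) in enumerate(
                zip(differences.estimates, differences.lower, differences.upper)
            ):
                ax.errorbar(est, row, xerr=[[est - lo], [hi - est]],
                            fmt="o", markersize=3, capsize=2, color="black")
                entries.append({"contrast": names[row], "estimate": float(est),
                                "lower": float(lo), "upper": float(hi)})
            ax.set_yticks(range(len(names)))
            ax.set_yticklabels(names, fontsize=6)
            ax.set_title("differences of means")
            layers["differences"] = entries

    result = PlotResult(fig, layers)
    if path is not None:
        result.save(path)
    return result
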