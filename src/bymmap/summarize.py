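"""Posterior reporting: relative risks, credible intervals, risk classes, maps.

Per-area relative risks are summarized by the posterior mean (the reported
point estimate, matching BUGS-lineage convention) and median, an equal-tailed
95% credible interval, and the exceedance probability P(theta_i > 1 | data).
Global diagnostics (DIC, pD, mean deviance, acceptance rates) ride along.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .areal_data import AreaTable, ValidationError
from .mcmc import ChainOutput, DICResult, dic

#: Default risk-class bin edges on the relative-risk scale (six classes).
DEFAULT_RISK_EDGES: tuple[float, ...] = (0.8, 0.95, 1.05, 1.25, 1.5)

MIN_DRAWS = 40  # fewer draws make the 2.5% tail quantile meaningless


@dataclass
class PosteriorSummary:
    """Per-area table plus global fit diagnostics.

    ``table`` is indexed by area_id with columns Y, E, smr, rr_mean,
    rr_median, cri_low, cri_high, prob_exceed_1.
    """

    table: pd.DataFrame
    dic: float
    p_d: float
    d_bar: float
    acceptance: dict[str, float]

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=True, index_label="area_id")


def summarize(
    chain: ChainOutput, areas: AreaTable, min_draws: int = MIN_DRAWS
) -> PosteriorSummary:
    """Equal-tailed 95% credible intervals and exceedance from theta draws."""
    if chain.n_draws < min_draws:
        raise ValidationError(
            f"need at least {min_draws} retained draws to estimate the 2.5% "
            f"tails, got {chain.n_draws}"
        )
    if tuple(chain.area_ids) != tuple(areas.area_ids):
        raise ValidationError("chain and AreaTable area ids differ")
    theta = chain.theta
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "Y": areas.Y,
            "E": areas.E if areas.E is not None else np.nan,
            "smr": areas.Y / areas.E if areas.E is not None else np.nan,
            "rr_mean": theta.mean(axis=0),
            "rr_median": np.median(theta, axis=0),
            "cri_low": lo,
            "cri_high": hi,
            "prob_exceed_1": (theta > 1.0).mean(axis=0),
        },
        index=pd.Index(chain.area_ids, name="area_id"),
    )
    d = dic(chain, areas)
    return PosteriorSummary(
        table=table,
        dic=d.dic,
        p_d=d.p_d,
        d_bar=d.d_bar,
        acceptance=dict(chain.acceptance),
    )


def risk_labels(edges: Sequence[float] = DEFAULT_RISK_EDGES) -> list[str]:
    """Human-readable labels for the half-open risk classes."""
    labels = [f"<{edges[0]:g}"]
    labels += [f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">={edges[-1]:g}")
    return labels


def classify_risk(
    summary: PosteriorSummary | np.ndarray | Sequence[float],
    edges: Sequence[float] = DEFAULT_RISK_EDGES,
) -> np.ndarray:
    """Half-open risk classes [low, high) on the posterior-mean RR.

    A value exactly at an edge belongs to the upper bin.  Returns integer
    class indices 0..len(edges); :func:`risk_labels` names them.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValidationError("risk-class edges must be strictly increasing")
    if isinstance(summary, PosteriorSummary):
        rr = summary.table["rr_mean"].to_numpy()
    else:
        rr = np.asarray(summary, dtype=float)
    return np.digitize(rr, edges, right=False)


def export_map(
    summary: PosteriorSummary,
    polygons: str | Path | Mapping,
    path: str | Path,
    id_property: str = "area_id",
    edges: Sequence[float] = DEFAULT_RISK_EDGES,
) -> None:
    """Write a GeoJSON choropleth source: one feature per area.

    Property values are copied from the summary table verbatim (no
    recomputation); ``risk_class`` uses :func:`classify_risk` with *edges*.
    Coordinates pass through unchanged (lon/lat order as supplied).
    """
    if not isinstance(polygons, Mapping):
        with open(polygons, "r", encoding="utf-8") as fh:
            polygons = json.load(fh)
    geoms: dict[str, Mapping] = {}
    for feat in polygons.get("features", []):
        props = feat.get("properties") or {}
        if id_property in props:
            geoms[str(props[id_property])] = feat["geometry"]
    missing = sorted(set(summary.area_ids) - set(geoms))
    if missing:
        raise ValidationError(f"areas with no geometry: {missing}")
    classes = classify_risk(summary, edges)
    labels = risk_labels(edges)
    feats = []
    for k, aid in enumerate(summary.area_ids):
        row = summary.table.loc[aid]
        feats.append(
            {
                "type": "Feature",
                "geometry": geoms[aid],
                "properties": {
                    "area_id": aid,
                    "Y": int(row["Y"]),
                    "E": float(row["E"]),
                    "smr": float(row["smr"]),
                    "rr_mean": float(row["rr_mean"]),
                    "cri_low": float(row["cri_low"]),
                    "cri_high": float(row["cri_high"]),
                    "prob_exceed_1": float(row["prob_exceed_1"]),
                    "risk_class": labels[classes[k]],
                },
            }
        )
    out = {"type": "FeatureCollection", "features": feats}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh)


def plot_choropleth(
    summary: PosteriorSummary,
    polygons: str | Path | Mapping,
    column: str = "rr_mean",
    id_property: str = "area_id",
    ax=None,
):
    """Minimal static choropleth (requires matplotlib; polygons only)."""
    import matplotlib.pyplot as plt  # optional dependency, imported lazily
    from matplotlib.collections import PolyCollection
    from shapely.geometry import shape

    if not isinstance(polygons, Mapping):
        with open(polygons, "r", encoding="utf-8") as fh:
            polygons = json.load(fh)
    verts, vals = [], []
    lookup = summary.table[column]
    for feat in polygons.get("features", []):
        aid = str((feat.get("properties") or {}).get(id_property))
        if aid not in lookup.index:
            continue
        geom = shape(feat["geometry"])
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for p in polys:
            verts.append(np.asarray(p.exterior.coords))
            vals.append(float(lookup.loc[aid]))
    if ax is None:
        _, ax = plt.subplots()
    coll = PolyCollection(verts, array=np.asarray(vals), edgecolor="k", lw=0.3)
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    plt.colorbar(coll, ax=ax, label=column)
    return ax
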