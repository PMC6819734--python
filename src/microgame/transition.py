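"""The cooperation-competition transition plane.

Each network element (a clade node or a clade-pair edge) is placed in a
plane by its standardized mutualism strength (z of the log-product weight)
against its standardized parasitism strength (z of the log-ratio magnitude:
strength, not direction). The line through the observed maximum-mutualism
point and the observed maximum-parasitism point characterizes the
cooperation-to-competition transition: elements on or near the line sit in a
cooperation-competition steady state, elements below it display milder
interactions, and elements above it exert more intense interactions.

Standardization pools nodes and edges into one distribution per axis by
default (separate standardization is available), and makes the construction
invariant to the log base and to any affine rescaling of the raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_builder import PARASITISM, InteractionNetwork
from .taxa_io import ValidationError


def standardize_scores(values: dict) -> dict:
    """z-scores (x - mean)/SD with the unbiased SD; rejects constant input."""
    keys = list(values)
    if len(keys) < 2:
        raise ValidationError("need >= 2 elements to standardize")
    arr = np.asarray([values[k] for k in keys], dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant scores cannot be standardized")
    z = (arr - arr.mean()) / sd
    return dict(zip(keys, z.tolist()))


@dataclass
class TransitionPlane:
    """Standardized (mutualism, parasitism) embedding with the transition line.

    ``points`` is indexed by element key ((type, key) tuples) with columns
    z_mutualism, z_parasitism, distance (signed perpendicular distance to the
    line, positive = the more-intense side) and side (on/above/below).
    """

    points: pd.DataFrame
    anchor_max_mutualism: tuple
    anchor_max_parasitism: tuple
    tolerance: float = 1e-9

    def point(self, key) -> pd.Series:
        """Row for one element key (tuple keys and `.loc` do not mix well)."""
        return self.points.loc[[key]].iloc[0]

    def to_frame(self) -> pd.DataFrame:
        out = self.points.copy()
        out.insert(0, "element_type", [k[0] for k in out.index])
        out.insert(1, "clade_1", [str(k[1][0]) if k[0] == "edge" else str(k[1]) for k in out.index])
        out.insert(2, "clade_2", [str(k[1][1]) if k[0] == "edge" else "" for k in out.index])
        return out.reset_index(drop=True)


def _element_weights(network: InteractionNetwork, magnitudes: bool) -> dict:
    out = {}
    for k, w in network.nodes.items():
        out[("node", k)] = abs(w) if magnitudes else w
    for k, w in network.edges.items():
        out[("edge", k)] = abs(w) if magnitudes else w
    return out


def _signed_distance(points: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance to the line through p1, p2.

    Raw sign follows the left-hand side of the direction p1 -> p2; callers
    reorient it so positive means the chosen half-plane.
    """
    d = p2 - p1
    norm = np.hypot(*d)
    if norm == 0:
        raise ValidationError("degenerate transition line: anchor points coincide")
    # cross product of (p2-p1) with (points - p1), normalised
    return (d[0] * (points[:, 1] - p1[1]) - d[1] * (points[:, 0] - p1[0])) / norm


def build_transition_plane(
    mutualism_net: InteractionNetwork,
    parasitism_net: InteractionNetwork,
    pooled: bool = True,
    tolerance: float = 1e-9,
    anchors: tuple | None = None,
) -> TransitionPlane:
    """Embed shared elements of a mutualism/parasitism network pair.

    The parasitism axis uses weight magnitudes (larger over smaller):
    the plane plots strength, not direction. ``pooled=True`` standardizes
    nodes and edges as one distribution per axis; ``False`` standardizes
    them separately. ``anchors`` optionally overrides the observed
    maximum-mutualism / maximum-parasitism anchor elements.
    """
    if parasitism_net.interaction != PARASITISM:
        raise ValidationError("second network must be the parasitism network")
    mut = _element_weights(mutualism_net, magnitudes=False)
    par = _element_weights(parasitism_net, magnitudes=True)
    keys = sorted(set(mut) & set(par), key=str)
    if len(keys) < 3:
        raise ValidationError(f"need >= 3 shared elements, have {len(keys)}")

    def z_axis(values: dict) -> dict:
        if pooled:
            return standardize_scores({k: values[k] for k in keys})
        out = {}
        for etype in ("node", "edge"):
            sub = {k: values[k] for k in keys if k[0] == etype}
            if len(sub) >= 2:
                out.update(standardize_scores(sub))
            elif sub:
                raise ValidationError(
                    f"cannot standardize a single {etype} separately; use pooled=True"
                )
        return out

    zm = z_axis(mut)
    zp = z_axis(par)
    pts = np.array([[zm[k], zp[k]] for k in keys])
    if anchors is None:
        a_mut = keys[int(np.argmax(pts[:, 0]))]
        a_par = keys[int(np.argmax(pts[:, 1]))]
    else:
        a_mut, a_par = anchors
        for a in (a_mut, a_par):
            if a not in keys:
                raise ValidationError(f"anchor {a!r} is not an embedded element")
    p1 = np.array([zm[a_mut], zp[a_mut]])
    p2 = np.array([zm[a_par], zp[a_par]])
    dist = _signed_distance(pts, p1, p2)
    # positive = the half-plane of the (max mutualism, max parasitism) corner,
    # i.e. the side of more intense interactions
    corner = np.array([[pts[:, 0].max(), pts[:, 1].max()]])
    corner_side = _signed_distance(corner, p1, p2)[0]
    if corner_side < 0:
        dist = -dist
    side = np.where(np.abs(dist) <= tolerance, "on", np.where(dist > 0, "above", "below"))
    points = pd.DataFrame(
        {"z_mutualism": pts[:, 0], "z_parasitism": pts[:, 1],
         "distance": dist, "side": side},
        index=pd.Index(keys, tupleize_cols=False, name="element"),
    )
    return TransitionPlane(
        points=points,
        anchor_max_mutualism=a_mut,
        anchor_max_parasitism=a_par,
        tolerance=tolerance,
    )


def compare_planes(plane_1: TransitionPlane, plane_2: TransitionPlane) -> pd.DataFrame:
    """Per-element displacement between two planes (e.g. winter vs summer)."""
    shared = plane_1.points.index.intersection(plane_2.points.index)
    if len(shared) == 0:
        raise ValidationError("transition planes share no elements")
    a = plane_1.points.loc[shared]
    b = plane_2.points.loc[shared]
    out = pd.DataFrame(
        {
            "delta_z_mutualism": b["z_mutualism"] - a["z_mutualism"],
            "delta_z_parasitism": b["z_parasitism"] - a["z_parasitism"],
            "delta_distance": b["distance"] - a["distance"],
        },
        index=shared,
    )
    return out


def plot_transition_plane(plane: TransitionPlane, path) -> None:
    """Plain scatter export of a transition plane (no styling guarantees)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    pts = plane.points
    for etype, marker in (("node", "o"), ("edge", "s")):
        sub = pts[[k[0] == etype for k in pts.index]]
        ax.scatter(sub["z_mutualism"], sub["z_parasitism"], marker=marker, label=etype)
    p1 = pts.loc[[plane.anchor_max_mutualism]]
    p2 = pts.loc[[plane.anchor_max_parasitism]]
    ax.plot(
        [p1["z_mutualism"].iloc[0], p2["z_mutualism"].iloc[0]],
        [p1["z_parasitism"].iloc[0], p2["z_parasitism"].iloc[0]],
        "k--",
    )
    ax.set_xlabel("standardized mutualism (z of log product)")
    ax.set_ylabel("standardized parasitism (z of |log ratio|)")
    ax.legend()
    fig.savefig(path)
    plt.close(fig)
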