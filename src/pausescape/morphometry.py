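"""Sholl analysis and neurite morphometry on traced neurons.

The analysis is planar: circles of radius 10, 20, ... um are drawn around
the soma and the number of neurite crossings is counted at each circle.
Scalar metrics (longest and total neurite length, primary neurites, branch
points) are compared between genotypes with unpaired t-tests; Sholl curves
with a balanced two-way fixed-effects ANOVA (genotype x radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import NeuronTrace, ValidationError
from .stats import TestResult, t_test_unpaired, two_way_anova

__all__ = [
    "ShollProfile",
    "MorphometricSummary",
    "sholl_profile",
    "neurite_metrics",
    "compare_morphometrics",
    "sholl_anova",
]

SCALAR_METRICS = ("longest_neurite_um", "total_length_um", "n_primary", "n_branch_points")


@dataclass
class ShollProfile:
    radius_step_um: float
    radii: np.ndarray  # step, 2*step, ... up to the arbor extent
    crossings: np.ndarray  # intersections per circle

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.crossings = np.asarray(self.crossings, dtype=int)
        if self.radii.size != self.crossings.size:
            raise ValidationError("radii/crossings length mismatch")
        if self.radii.size and (np.any(np.diff(self.radii) <= 0) or self.radii[0] != self.radius_step_um):
            raise ValidationError("radii must be increasing multiples of the step")
        if self.crossings.size and self.crossings.min() < 0:
            raise ValidationError("crossings must be >= 0")


@dataclass
class MorphometricSummary:
    longest_neurite_um: float
    total_length_um: float
    n_primary: int
    n_branch_points: int

    def __post_init__(self) -> None:
        if self.longest_neurite_um > self.total_length_um + 1e-9:
            raise ValidationError("longest path cannot exceed total length")
        if self.n_primary < 1:
            raise ValidationError("a traced neuron has >= 1 primary neurite")


def _segment_circle_crossings(ax, ay, bx, by, r: float) -> int:
    """Number of intersection points of segment A->B with the circle of
    radius r about the origin, counting t in (0, 1] so that a node exactly
    on the circle is attributed to its incoming segment only."""
    dx, dy = bx - ax, by - ay
    a = dx * dx + dy * dy
    if a == 0:
        return 0
    b = 2.0 * (ax * dx + ay * dy)
    c = ax * ax + ay * ay - r * r
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return 0
    sq = math.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 < t <= 1.0:
            count += 1
    if disc == 0 and count == 2:  # tangent point counted once
        count = 1
    return count


def sholl_profile(trace: NeuronTrace, step_um: float = 10.0) -> ShollProfile:
    """Crossing counts at circles of radius step, 2*step, ... around the soma.

    Radii run to the largest multiple of the step reachable by the arbor
    (a circle beyond the farthest node can never be crossed); a soma-only
    trace, or one whose arbor stays inside the first circle, yields an empty
    profile.  Crossings are actual circle-segment intersection points (a
    tangent touch counts once).
    """
    if step_um <= 0:
        raise ValidationError("step must be > 0")
    soma = trace.root
    segs = trace.segments()
    if not segs:
        return ShollProfile(step_um, np.array([]), np.array([], dtype=int))
    max_dist = max(math.hypot(n.x - soma.x, n.y - soma.y) for n in trace.nodes)
    n_radii = math.floor(max_dist / step_um)
    radii = step_um * np.arange(1, n_radii + 1)
    crossings = np.zeros(n_radii, dtype=int)
    for parent, child in segs:
        ax, ay = parent.x - soma.x, parent.y - soma.y
        bx, by = child.x - soma.x, child.y - soma.y
        for i, r in enumerate(radii):
            crossings[i] += _segment_circle_crossings(ax, ay, bx, by, float(r))
    return ShollProfile(step_um, radii, crossings)


def neurite_metrics(trace: NeuronTrace) -> MorphometricSummary:
    """Euclidean morphometrics of one trace.

    longest = max root-to-leaf path length; total = sum of segment lengths;
    primary = children of the soma; branch points = non-soma nodes with
    >= 2 children.
    """
    if not trace.segments():
        raise ValidationError("trace has no neurite segments")
    soma = trace.root
    total = 0.0
    path_to: dict[int, float] = {soma.node_id: 0.0}
    longest = 0.0
    n_branch = 0
    for node in trace.nodes:
        if node.parent_id == -1:
            continue
        parent = trace.node(node.parent_id)
        seg = math.hypot(node.x - parent.x, node.y - parent.y)
        total += seg
        path_to[node.node_id] = path_to[parent.node_id] + seg
        longest = max(longest, path_to[node.node_id])
        if node.node_id != soma.node_id and len(trace.children(node.node_id)) >= 2:
            n_branch += 1
    return MorphometricSummary(
        longest_neurite_um=longest,
        total_length_um=total,
        n_primary=len(trace.children(soma.node_id)),
        n_branch_points=n_branch,
    )


def compare_morphometrics(
    group_a: list[MorphometricSummary], group_b: list[MorphometricSummary]
) -> dict[str, TestResult]:
    """Unpaired two-sided t-test per scalar metric (a vs b)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 neurons per group")
    out = {}
    for metric in SCALAR_METRICS:
        a = [float(getattr(s, metric)) for s in group_a]
        b = [float(getattr(s, metric)) for s in group_b]
        out[metric] = t_test_unpaired(a, b)
    return out


def align_profiles(profiles: list[ShollProfile], n_radii: int | None = None) -> np.ndarray:
    """Stack crossing counts over a common radius range.

    With ``n_radii`` given, profiles are truncated or zero-padded to that
    length (circles beyond the arbor have zero crossings); otherwise all
    profiles must already share one length.
    """
    steps = {p.radius_step_um for p in profiles}
    if len(steps) != 1:
        raise ValidationError("profiles use different radius steps")
    lengths = {p.crossings.size for p in profiles}
    if n_radii is None:
        if len(lengths) != 1:
            raise ValidationError(
                "profiles span different radius ranges; pass n_radii to truncate/pad"
            )
        n_radii = lengths.pop()
    out = np.zeros((len(profiles), n_radii), dtype=int)
    for i, p in enumerate(profiles):
        m = min(n_radii, p.crossings.size)
        out[i, :m] = p.crossings[:m]
    return out


def sholl_anova(
    profiles_a: list[ShollProfile],
    profiles_b: list[ShollProfile],
    n_radii: int | None = None,
) -> dict[str, TestResult]:
    """Two-way fixed-effects ANOVA (genotype x radius) on crossing counts.

    Requires a balanced layout: equal neuron counts are not needed by the
    model, but every genotype x radius cell must hold the same number of
    crossing counts, which holds when both groups have equal size.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValidationError("need >= 2 profiles per group")
    mat_a = align_profiles(profiles_a, n_radii)
    mat_b = align_profiles(profiles_b, n_radii)
    if mat_a.shape[1] != mat_b.shape[1]:
        common = min(mat_a.shape[1], mat_b.shape[1])
        mat_a, mat_b = mat_a[:, :common], mat_b[:, :common]
    values, genotype, radius = [], [], []
    for label, mat in (("a", mat_a), ("b", mat_b)):
        for row in mat:
            for j, v in enumerate(row):
                values.append(float(v))
                genotype.append(label)
                radius.append(j)
    return two_way_anova(values, genotype, radius)
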