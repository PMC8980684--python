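"""Shared fixtures and independent oracles."""
from __future__ import annotations

import numpy as np
import pytest

from ctffr.geometry import Lesion, VesselTree, apply_lesions, make_segment
from ctffr.hemodynamics import BloodModel, BoundaryParams

PA_PER_MMHG = 133.322


@pytest.fixture
def blood() -> BloodModel:
    return BloodModel()


@pytest.fixture
def params() -> BoundaryParams:
    return BoundaryParams()


@pytest.fixture
def tube_tree():
    """Single uniform 3 mm x 10 mm tube (the two-resistor analytic case)."""
    seg = make_segment(10.0, 3.0, 3.0, 5, segment_id="s0")
    return VesselTree.from_segments([seg], "LAD")


@pytest.fixture
def bifurcation_tree():
    """Perfectly symmetric bifurcation."""
    trunk = make_segment(20.0, 3.4, 3.0, segment_id="t", is_outlet=False)
    left = make_segment(25.0, 2.9, 2.2, segment_id="l", parent_id="t")
    right = make_segment(25.0, 2.9, 2.2, segment_id="r", parent_id="t")
    return VesselTree.from_segments([trunk, left, right], "LAD")


@pytest.fixture
def stenosed_vessel():
    """3-segment LAD-like tree with a 60% mid-trunk lesion applied."""
    trunk = make_segment(40.0, 3.2, 2.95, segment_id="prox", is_outlet=False)
    dist = make_segment(35.0, 2.8, 2.2, segment_id="dist", parent_id="prox")
    side = make_segment(25.0, 2.2, 1.9, segment_id="side", parent_id="prox")
    tree = VesselTree.from_segments([trunk, dist, side], "LAD")
    lesion = Lesion("prox", 10.0, 18.0, 60.0)
    return apply_lesions(tree, [lesion]), lesion


def random_tree(rng: np.random.Generator, max_segments: int = 50) -> VesselTree:
    """Random rooted tree with tapering calibres, no lesions."""
    n_target = int(rng.integers(1, max_segments + 1))
    segments = []
    counter = [0]

    def add(parent_id, prox_d, budget):
        sid = f"s{counter[0]}"
        counter[0] += 1
        length = float(rng.uniform(5.0, 35.0))
        dist_d = prox_d * float(rng.uniform(0.72, 0.96))
        n_children = int(rng.integers(0, 3)) if budget > 1 and dist_d > 1.2 else 0
        n_children = max(0, min(n_children, budget - 1))
        segments.append(
            make_segment(length, prox_d, dist_d, segment_id=sid, parent_id=parent_id,
                         is_outlet=n_children == 0)
        )
        budget -= 1
        for _ in range(n_children):
            child_d = dist_d * float(rng.uniform(0.75, 1.0))
            budget = add(sid, child_d, budget)
        return budget

    add(None, float(rng.uniform(3.0, 4.2)), n_target)
    return VesselTree.from_segments(segments, "LAD")


def linear_network_oracle(tree: VesselTree, params: BoundaryParams, blood: BloodModel):
    """Independent linear (K_t = 0) solve via a sparse nodal Laplacian.

    Re-derives every coefficient from first principles (piecewise Poiseuille
    resistance per sampled interval, power-law outlet resistance) and solves
    the assembled system with scipy's sparse direct solver.  Returns
    (junction pressures by segment id, segment flows by id).
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    order = list(tree.segments)
    idx = {sid: i for i, sid in enumerate(order)}
    n = len(order)
    mat = lil_matrix((n, n))
    rhs = np.zeros(n)
    mu = blood.dynamic_viscosity
    for sid in order:
        seg = tree.segments[sid]
        # independent trapezoid of the viscous integrand, interval by interval
        res_si = 0.0
        for i in range(seg.arc.size - 1):
            f0 = 8.0 * mu / (np.pi * (seg.lumen_radius[i] * 1e-3) ** 4)
            f1 = 8.0 * mu / (np.pi * (seg.lumen_radius[i + 1] * 1e-3) ** 4)
            res_si += 0.5 * (f0 + f1) * (seg.arc[i + 1] - seg.arc[i]) * 1e-3
        g = 1.0 / (res_si * 1e-6 / PA_PER_MMHG)
        j = idx[sid]
        mat[j, j] += g
        if seg.parent_id is None:
            rhs[j] += g * params.aortic_pressure
        else:
            pj = idx[seg.parent_id]
            mat[j, pj] -= g
            mat[pj, j] -= g
            mat[pj, pj] += g
        if seg.is_outlet:
            r_out = (
                params.outlet_resistance_scale
                / params.hyperemia_factor
                * (seg.dist_reference_diameter / params.reference_diameter)
                ** (-params.diameter_exponent)
            )
            mat[j, j] += 1.0 / r_out
    p = spsolve(mat.tocsr(), rhs)
    pressures = {sid: float(p[idx[sid]]) for sid in order}
    flows = {}
    for sid in order:
        seg = tree.segments[sid]
        up = params.aortic_pressure if seg.parent_id is None else pressures[seg.parent_id]
        res_si = 0.0
        for i in range(seg.arc.size - 1):
            f0 = 8.0 * mu / (np.pi * (seg.lumen_radius[i] * 1e-3) ** 4)
            f1 = 8.0 * mu / (np.pi * (seg.lumen_radius[i + 1] * 1e-3) ** 4)
            res_si += 0.5 * (f0 + f1) * (seg.arc[i + 1] - seg.arc[i]) * 1e-3
        flows[sid] = (up - pressures[sid]) / (res_si * 1e-6 / PA_PER_MMHG)
    return pressures, flows
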