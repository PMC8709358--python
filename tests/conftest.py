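import math

import numpy as np
import pytest

from gammasec.disorder import DEFAULT_CHARGE, KYTE_DOOLITTLE, ScorerParams
from gammasec.sequences import load_catalog, load_window


@pytest.fixture
def app_window():
    return load_window("APP")


@pytest.fixture
def d1_window():
    return load_window("PS1_D1")


@pytest.fixture
def d2_window():
    return load_window("PS1_D2")


def brute_force_scores(seq: str, params: ScorerParams | None = None) -> list[float]:
    """Independent loop-based reimplementation of the disorder scorer.

    Deliberately unvectorised: explicit python loops and math only, used as
    the oracle for score_profile.
    """
    p = params or ScorerParams()
    half = p.window_width // 2
    out = []
    for i in range(len(seq)):
        lo = i - half if i - half > 0 else 0
        hi = i + half + 1 if i + half + 1 < len(seq) else len(seq)
        total_h = 0.0
        total_q = 0.0
        count = 0
        for j in range(lo, hi):
            total_h += (p.hydropathy_scale[seq[j]] + 4.5) / 9.0
            total_q += p.charge_map.get(seq[j], 0.0)
            count += 1
        fold_index = p.coeff_h * (total_h / count) - abs(total_q / count) - p.coeff_c
        out.append(1.0 / (1.0 + math.exp(p.steepness * fold_index)))
    return out


def quaternion_superpose_rmsd(mov: np.ndarray, ref: np.ndarray) -> float:
    """Horn's quaternion method: optimal rigid-superposition RMSD.

    Independent of the SVD Kabsch path — builds the 4x4 key matrix from the
    correlation tensor and takes its largest eigenvalue.
    """
    P = mov - mov.mean(axis=0)
    Q = ref - ref.mean(axis=0)
    S = P.T @ Q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    e2 = (P ** 2).sum() + (Q ** 2).sum() - 2.0 * lam_max
    return math.sqrt(max(e2, 0.0) / len(P))


def brute_force_contacts(model, chain_a, chain_b, cutoff):
    """All-pairs enumeration oracle for contact_map."""
    best = {}
    for a in model.atoms:
        if a.chain != chain_a:
            continue
        for b in model.atoms:
            if b.chain != chain_b:
                continue
            d = math.dist(a.pos, b.pos)
            if d <= cutoff:
                key = (a.reskey, b.reskey)
                if d < best.get(key, math.inf):
                    best[key] = d
    return best


def cone_expansion_oracle(footprint_nm: float, span_nm: float, outer_nm: float) -> float:
    """Numeric construction of the equal-angle cone between the two leaflet
    spheres; returns the cytosolic chord expansion in Å."""
    r_cyt = outer_nm / 2.0
    r_lum = r_cyt - span_nm
    half_chord = footprint_nm / 2.0
    # luminal footprint rim point on the inner sphere
    z = math.sqrt(r_lum ** 2 - half_chord ** 2)
    rim = np.array([half_chord, 0.0, z])
    # extend the apex ray (from the vesicle centre) to the outer sphere
    rim_out = rim * (r_cyt / np.linalg.norm(rim))
    # the cone is rotationally symmetric: the outer chord diameter is twice
    # the transverse radius of the extended rim point
    d_nm = 2.0 * rim_out[0] - footprint_nm
    return d_nm * 10.0
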