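import numpy as np
import pytest

from lnpsim.forcefield import default_forcefield
from lnpsim.system import SystemSpec, build_system, compile_system
from lnpsim.topology import build_tripalmitin, build_tween20, build_water_bead


@pytest.fixture(scope="session")
def tables():
    return default_forcefield()


@pytest.fixture(scope="session")
def tripalmitin(tables):
    return build_tripalmitin(tables)


@pytest.fixture(scope="session")
def tween20(tables):
    return build_tween20(tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def water_box_topology(tables):
    """50 CG water beads (45 P4 + 5 AF) compiled for kernel tests."""
    mols = [build_water_bead("P4")] * 45 + [build_water_bead("AF")] * 5
    return compile_system(mols, tables)


@pytest.fixture(scope="session")
def small_mixed_state(tables):
    """Small solvated lipid system reused by engine tests."""
    spec = SystemSpec(4, 0, 150, 15, 3.6, seed=7, name="mixed")
    return build_system(spec, tables=tables)


def brute_force_reference(positions, box, topo, r_on=1.0, r_cut=1.4):
    """All-pairs O(N^2) numpy evaluation of the switched-LJ + bonded
    potential: the independent oracle for the kernel forces."""
    n = positions.shape[0]
    sig = topo.sigma[np.ix_(topo.type_idx, topo.type_idx)]
    eps = topo.eps[np.ix_(topo.type_idx, topo.type_idx)]
    d = positions[:, None, :] - positions[None, :, :]
    d -= box * np.rint(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    # exclusion mask from CSR arrays
    excl = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in topo.excl_idx[topo.excl_indptr[i]: topo.excl_indptr[i + 1]]:
            excl[i, j] = True
    ron2, rc2 = r_on**2, r_cut**2
    inv_den = 1.0 / (rc2 - ron2) ** 3
    with np.errstate(over="ignore", invalid="ignore"):
        sr2 = sig**2 / r2
        sr6 = sr2**3
        sr12 = sr6**2
        v = 4 * eps * (sr12 - sr6)
        fs = 24 * eps * (2 * sr12 - sr6) / r2
        a = rc2 - r2
        sw = np.where(r2 > ron2, a * a * (rc2 + 2 * r2 - 3 * ron2) * inv_den, 1.0)
        dsw = np.where(r2 > ron2, 6 * a * (ron2 - r2) * inv_den, 0.0)
        active = (r2 < rc2) & ~excl
        fs_t = np.where(active, fs * sw - 2 * v * dsw, 0.0)
        v_t = np.where(active, v * sw, 0.0)
    energy = 0.5 * float(v_t.sum())
    forces = np.einsum("ij,ijk->ik", fs_t, d)

    for (i, j), r0, k in zip(topo.bonds, topo.bond_r0, topo.bond_k):
        dv = positions[i] - positions[j]
        dv -= box * np.rint(dv / box)
        r = np.linalg.norm(dv)
        energy += 0.5 * k * (r - r0) ** 2
        f = -k * (r - r0) * dv / r
        forces[i] += f
        forces[j] -= f
    for (i, j, m), c0, k in zip(topo.angles, topo.angle_cos0, topo.angle_k):
        u = positions[i] - positions[j]
        u -= box * np.rint(u / box)
        v_ = positions[m] - positions[j]
        v_ -= box * np.rint(v_ / box)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v_)
        c = np.clip(u @ v_ / (nu * nv), -1, 1)
        energy += 0.5 * k * (c - c0) ** 2
        g = -k * (c - c0)
        fi = g * (v_ / (nu * nv) - c * u / nu**2)
        fm = g * (u / (nu * nv) - c * v_ / nv**2)
        forces[i] += fi
        forces[m] += fm
        forces[j] -= fi + fm
    return energy, forces
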