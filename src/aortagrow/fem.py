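"""Small-strain linear elasticity on 8-node hexahedra.

Vectorized assembly with 2x2x2 Gauss integration and a mean-dilatation
(B-bar) treatment of the volumetric strain, which keeps the element
usable up to nearly incompressible Poisson ratios.  Units are mm / kPa,
so forces come out in mN and displacements in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["FEMResult", "solve_elasticity", "traction_forces", "hex_jacobians"]

# natural coordinates of the standard trilinear hex
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_GP = np.array([[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)],
               dtype=float) / np.sqrt(3.0)


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/dxi at one natural point; shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = 0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2])
        g[a, 1] = 0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2])
        g[a, 2] = 0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1])
    return g

_DN = np.stack([_shape_gradients(gp) for gp in _GP])   # (8 gp, 8 nodes, 3)


def _elastic_matrix(E: float | np.ndarray, nu: float) -> np.ndarray:
    """Isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            C[:, i, j] = lam
        C[:, i, i] += 2 * mu
    for i in range(3, 6):
        C[:, i, i] = mu
    return C


def hex_jacobians(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """det J at every Gauss point of every element, shape (E, 8)."""
    X = nodes[hexes]                                   # (E, 8, 3)
    J = np.einsum("gai,eaj->egij", _DN, X)             # (E, 8gp, 3, 3)
    return np.linalg.det(J)


def _b_matrices(X: np.ndarray):
    """B-bar strain-displacement matrices and Gauss weights.

    Parameters: X (E, 8, 3) element node coordinates.
    Returns (Bbar (E, 8gp, 6, 24), detJ (E, 8gp)).
    """
    J = np.einsum("gai,eaj->egij", _DN, X)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.unique(np.argwhere(detJ <= 0)[:, 0])[:10]
        raise ValueError(f"non-positive Jacobian in elements {bad.tolist()}")
    Jinv = np.linalg.inv(J)
    # J_ij = dx_j/dxi_i, so dxi_i/dx_j = (J^-1)_ji and dN/dx_j = (J^-1)_ji dN/dxi_i
    dNdx = np.einsum("egji,gai->egaj", Jinv, _DN)      # (E, 8gp, 8, 3)

    E_n = X.shape[0]
    B = np.zeros((E_n, 8, 6, 24))
    a_idx = np.arange(8)
    B[:, :, 0, a_idx * 3 + 0] = dNdx[:, :, :, 0]
    B[:, :, 1, a_idx * 3 + 1] = dNdx[:, :, :, 1]
    B[:, :, 2, a_idx * 3 + 2] = dNdx[:, :, :, 2]
    B[:, :, 3, a_idx * 3 + 0] = dNdx[:, :, :, 1]
    B[:, :, 3, a_idx * 3 + 1] = dNdx[:, :, :, 0]
    B[:, :, 4, a_idx * 3 + 1] = dNdx[:, :, :, 2]
    B[:, :, 4, a_idx * 3 + 2] = dNdx[:, :, :, 1]
    B[:, :, 5, a_idx * 3 + 0] = dNdx[:, :, :, 2]
    B[:, :, 5, a_idx * 3 + 2] = dNdx[:, :, :, 0]

    # mean-dilatation B-bar: replace the volumetric part of the normal
    # rows by its volume average over the element
    Bvol = B[:, :, 0:3, :].mean(axis=2)                         # (E, gp, 24)
    w = detJ / detJ.sum(axis=1, keepdims=True)
    Bvol_bar = np.einsum("eg,egk->ek", w, Bvol)                 # (E, 24)
    Bbar = B.copy()
    Bbar[:, :, 0:3, :] += Bvol_bar[:, None, None, :] - Bvol[:, :, None, :]
    return Bbar, detJ


@dataclass
class FEMResult:
    """Displacements and recovered stresses of one elastostatic solve."""

    displacement: np.ndarray      # (N, 3) mm
    element_stress: np.ndarray    # (E, 6) kPa, Voigt, element volume average
    node_stress: np.ndarray       # (N, 6) kPa, volume-weighted nodal average
    max_principal: np.ndarray     # (N,) kPa
    von_mises: np.ndarray         # (N,) kPa

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=1).max())


def _voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    T = np.empty(v.shape[:-1] + (3, 3))
    T[..., 0, 0] = v[..., 0]
    T[..., 1, 1] = v[..., 1]
    T[..., 2, 2] = v[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = v[..., 3]
    T[..., 1, 2] = T[..., 2, 1] = v[..., 4]
    T[..., 0, 2] = T[..., 2, 0] = v[..., 5]
    return T


def solve_elasticity(nodes: np.ndarray, hexes: np.ndarray,
                     youngs: np.ndarray, nu: float,
                     forces: np.ndarray, fixed_dofs: np.ndarray) -> FEMResult:
    """Assemble and solve K u = f with clamped dofs eliminated.

    Parameters
    ----------
    youngs : (E,) per-element Young's modulus, kPa.
    forces : (N, 3) consistent nodal loads, mN.
    fixed_dofs : flat dof indices (3*node + component) held at zero.
    """
    nodes = np.asarray(nodes, dtype=float)
    hexes = np.asarray(hexes, dtype=np.int64)
    n_dof = 3 * len(nodes)
    X = nodes[hexes]
    Bbar, detJ = _b_matrices(X)
    C = _elastic_matrix(youngs, nu)                      # (E, 6, 6)
    # k_e = sum_gp B' C B detJ
    ke = np.einsum("egai,eab,egbj,eg->eij", Bbar, C, Bbar, detJ,
                   optimize=True)

    edof = (3 * hexes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    free = np.ones(n_dof, dtype=bool)
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    free[fixed_dofs] = False
    # nodes not referenced by any element (e.g. inside fenestration
    # holes) carry no stiffness; pin them
    used = np.zeros(len(nodes), dtype=bool)
    used[np.unique(hexes)] = True
    free[np.repeat(~used, 3)] = False
    if free.all():
        raise ValueError("no constraints: the system is singular")
    f = np.asarray(forces, dtype=float).ravel()
    Kff = K[free][:, free].tocsc()
    try:
        u_free = spla.spsolve(Kff, f[free])
    except RuntimeError as exc:   # pragma: no cover - singular systems
        raise ValueError(f"singular stiffness after constraints: {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise ValueError("singular stiffness after constraints (non-finite solution)")
    u = np.zeros(n_dof)
    u[free] = u_free

    ue = u[edof]                                         # (E, 24)
    strain = np.einsum("egij,ej->egi", Bbar, ue, optimize=True)
    stress_gp = np.einsum("eij,egj->egi", C, strain)
    wgt = detJ / detJ.sum(axis=1, keepdims=True)
    el_stress = np.einsum("eg,egi->ei", wgt, stress_gp)  # element volume average

    # volume-weighted extrapolation of element stresses to nodes
    vol = detJ.sum(axis=1)
    node_stress = np.zeros((len(nodes), 6))
    node_w = np.zeros(len(nodes))
    for a in range(8):
        np.add.at(node_stress, hexes[:, a], el_stress * vol[:, None])
        np.add.at(node_w, hexes[:, a], vol)
    node_w[node_w == 0] = 1.0
    node_stress /= node_w[:, None]

    T = _voigt_to_tensor(node_stress)
    eig = np.linalg.eigvalsh(T)
    max_principal = eig[:, -1]
    s = node_stress
    von = np.sqrt(0.5 * ((s[:, 0] - s[:, 1]) ** 2 + (s[:, 1] - s[:, 2]) ** 2
                         + (s[:, 2] - s[:, 0]) ** 2)
                  + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2))
    return FEMResult(displacement=u.reshape(-1, 3), element_stress=el_stress,
                     node_stress=node_stress, max_principal=max_principal,
                     von_mises=von)


def traction_forces(nodes: np.ndarray, facets: np.ndarray,
                    pressures: np.ndarray, hints: np.ndarray) -> np.ndarray:
    """Consistent nodal forces from facet pressures (kPa -> mN).

    Each quad is split into two triangles; the pressure acts along the
    facet normal oriented by the per-facet hint (lumen-to-solid
    direction), consistent with the undeformed-normal loading of a
    negligible-deformation penalty solve.
    """
    forces = np.zeros_like(nodes, dtype=float)
    quads = nodes[facets]                         # (F, 4, 3)
    g = 1.0 / np.sqrt(3.0)
    corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    for gx, gy in ((-g, -g), (g, -g), (g, g), (-g, g)):
        N = 0.25 * (1 + corners[:, 0] * gx) * (1 + corners[:, 1] * gy)   # (4,)
        dNdxi = 0.25 * corners[:, 0] * (1 + corners[:, 1] * gy)
        dNdeta = 0.25 * corners[:, 1] * (1 + corners[:, 0] * gx)
        t_xi = np.einsum("a,fai->fi", dNdxi, quads)
        t_eta = np.einsum("a,fai->fi", dNdeta, quads)
        an = np.cross(t_xi, t_eta)                # area-scaled normal at gp
        sign = np.sign(np.einsum("fi,fi->f", an, hints))
        sign[sign == 0] = 1.0
        fvec = (pressures * sign)[:, None] * an   # Gauss weight 1
        for a in range(4):
            np.add.at(forces, facets[:, a], N[a] * fvec)
    return forces
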