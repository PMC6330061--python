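"""Random close packing of cells into 3D clusters and monolayers.

Spheroids are modeled as disordered packings of spherical cells with
correlated, empirically distributed cell and nucleus radii.  Packing proceeds
in two stages, mirroring the way disordered tissue models are usually built:

1. *Monodisperse densification* — equal spheres in a periodic box are grown
   while overlap is relaxed away by a force-biased collective-rearrangement
   scheme with momentum and occasional shake moves (a practical, vectorized
   relative of event-driven compression algorithms).  The process jams at a
   volume fraction of ~0.63, the random-close-packing regime.
2. *Carving and radius assignment* — a ball (cluster) or disk (monolayer) of
   ``n`` centers is carved from the periodic packing, radii are drawn from a
   truncated correlated bivariate normal distribution, matched to centers by
   a rank-preserving rule (roomier sites get larger cells), and the center
   coordinates are rescaled so the realized cell-volume fraction hits the
   requested target (far below jamming for loosely associated spheroids).

All randomness flows through a single integer seed; identical seeds produce
bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CellInstance",
    "SpheroidModel",
    "RadiiDistribution",
    "PackingError",
    "generate_rcp_centers",
    "sample_radii",
    "build_assembly",
    "peripheral_mask",
    "audit_overlaps",
]

OVERLAP_TOL = 1e-3          # relative center-distance tolerance at the RCP stage
GAP_TOL_FRACTION = 0.01     # allowed overlap: gap >= -0.01 * min radius


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CellInstance:
    id: int
    center: np.ndarray  # (3,) um
    R_c: float
    R_n: float


@dataclass
class SpheroidModel:
    """A packed assembly of cells.

    Arrays are aligned by cell index: ``centers`` (n, 3) in um with the
    assembly centered at the origin, ``R_c``/``R_n`` per-cell radii in um.
    ``bounding_radius`` is the radius of the sphere (or disk, for
    monolayers) containing every cell entirely; ``packing_fraction`` the
    realized cell-volume (or cell-area) fraction inside it;
    ``rcp_packing_fraction`` the volume fraction reached by the monodisperse
    densification stage before carving.
    """

    centers: np.ndarray
    R_c: np.ndarray
    R_n: np.ndarray
    mode: str
    seed: int
    bounding_radius: float
    packing_fraction: float
    rcp_packing_fraction: float

    def __post_init__(self):
        if self.centers.shape[0] < 1:
            raise ValueError("model must contain at least one cell")
        if self.mode not in ("cluster", "monolayer"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    @property
    def radial_distance(self) -> np.ndarray:
        return np.linalg.norm(self.centers, axis=1)

    def cells(self):
        for i in range(self.n_cells):
            yield CellInstance(i, self.centers[i], float(self.R_c[i]),
                               float(self.R_n[i]))

    def to_csv(self, path: str | Path) -> None:
        """Write the model as CSV with a commented metadata header."""
        path = Path(path)
        with open(path, "w") as f:
            f.write(f"# mode={self.mode} seed={self.seed} "
                    f"bounding_radius_um={self.bounding_radius:.6g} "
                    f"packing_fraction={self.packing_fraction:.6g} "
                    f"rcp_packing_fraction={self.rcp_packing_fraction:.6g}\n")
            f.write("id,x_um,y_um,z_um,R_c_um,R_n_um\n")
            for c in self.cells():
                f.write(f"{c.id},{c.center[0]:.6f},{c.center[1]:.6f},"
                        f"{c.center[2]:.6f},{c.R_c:.6f},{c.R_n:.6f}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpheroidModel":
        path = Path(path)
        meta = {}
        with open(path) as f:
            header = f.readline()
            for tok in header.lstrip("#").split():
                k, _, v = tok.partition("=")
                meta[k] = v
        arr = np.loadtxt(path, delimiter=",", skiprows=2)
        arr = np.atleast_2d(arr)
        return cls(centers=arr[:, 1:4], R_c=arr[:, 4], R_n=arr[:, 5],
                   mode=meta["mode"], seed=int(meta["seed"]),
                   bounding_radius=float(meta["bounding_radius_um"]),
                   packing_fraction=float(meta["packing_fraction"]),
                   rcp_packing_fraction=float(meta["rcp_packing_fraction"]))


@dataclass(frozen=True)
class RadiiDistribution:
    """Correlated cell/nucleus radius distribution (truncated bivariate normal).

    ``rho`` is the correlation between cell and nucleus radius; samples with
    ``R_n >= fmax * R_c`` (or non-positive radii) are rejected, which keeps
    every nucleus strictly inside its cell.
    """

    mean_Rc: float
    sd_Rc: float
    mean_Rn: float
    sd_Rn: float
    rho: float = 0.7
    min_radius: float = 0.5   # um; lower truncation of both radii
    fmax: float = 0.95        # max allowed R_n / R_c

    def __post_init__(self):
        if self.sd_Rc < 0 or self.sd_Rn < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if not 0 < self.fmax < 1.0 or self.mean_Rn >= self.mean_Rc:
            raise ValueError("mean nucleus radius must be below mean cell radius")


def sample_radii(dist: RadiiDistribution, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` correlated (R_c, R_n) pairs.

    Cell radii are drawn from their unbiased marginal (rejecting only
    non-positive values, which are many sigma out for realistic cells);
    nucleus radii come from the conditional normal given R_c, truncated to
    ``(min_radius, fmax * R_c)`` so every nucleus fits strictly inside its
    cell without biasing the cell-size distribution.
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(seed)
    out_c = np.empty(n)
    filled = 0
    attempts = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        attempts += m
        rc = dist.mean_Rc + dist.sd_Rc * rng.standard_normal(m)
        ok = rc > dist.min_radius
        take = min(ok.sum(), n - filled)
        out_c[filled:filled + take] = rc[ok][:take]
        filled += take
        if attempts > 100 * n + 1000:
            raise PackingError(
                "radius sampling rejection rate above 99%; "
                "distribution truncation is infeasible")
    rc = out_c
    z1 = (rc - dist.mean_Rc) / dist.sd_Rc if dist.sd_Rc > 0 else np.zeros(n)
    mean_cond = dist.mean_Rn + dist.rho * dist.sd_Rn * z1
    sd_cond = dist.sd_Rn * np.sqrt(max(0.0, 1.0 - dist.rho**2))
    hi = dist.fmax * rc
    if sd_cond == 0.0:
        rn = mean_cond
        if np.any((rn >= hi) | (rn <= dist.min_radius)):
            raise PackingError(
                "degenerate nucleus-radius distribution falls outside the "
                "feasible window R_n in (min_radius, fmax * R_c)")
    else:
        a = (dist.min_radius - mean_cond) / sd_cond
        b = (hi - mean_cond) / sd_cond
        if np.any(b <= a) or np.any(b < -8.0):
            raise PackingError(
                "truncation window for nucleus radii is empty or has "
                "negligible probability mass; distribution is infeasible")
        # shift the conditional location so the *truncated* mean stays on
        # target (truncation alone would bias nuclei small)
        from scipy.stats import norm

        delta = np.zeros(n)
        for _ in range(4):
            aa = a - delta / sd_cond
            bb = b - delta / sd_cond
            mass = np.maximum(norm.cdf(bb) - norm.cdf(aa), 1e-12)
            shift = sd_cond * (norm.pdf(aa) - norm.pdf(bb)) / mass
            delta = np.clip(-shift, -2.0 * sd_cond, 2.0 * sd_cond)
        rn = truncnorm.rvs(a - delta / sd_cond, b - delta / sd_cond,
                           loc=mean_cond + delta, scale=sd_cond,
                           size=n, random_state=rng)
    return rc, rn


def _relax(pos, vel, rr, nsw, rng, *, push=0.6, beta=0.6, tol=OVERLAP_TOL):
    """Push overlapping spheres apart (periodic box, momentum-assisted)."""
    for _ in range(nsw):
        tree = cKDTree(pos, boxsize=1.0)
        pairs = tree.query_pairs(2 * rr, output_type="ndarray")
        if len(pairs) == 0:
            return True
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[i] - pos[j]
        d -= np.round(d)
        dist = np.linalg.norm(d, axis=1)
        ov = 2 * rr - dist
        bad = ov > rr * tol
        if not bad.any():
            return True
        i, j, d, dist, ov = i[bad], j[bad], d[bad], dist[bad], ov[bad]
        mv = (push * ov / dist)[:, None] * d
        force = np.zeros_like(pos)
        np.add.at(force, i, mv)
        np.add.at(force, j, -mv)
        vel *= beta
        vel += force
        pos += vel
        np.mod(pos, 1.0, out=pos)
    return False


def generate_rcp_centers(n: int, seed, *, dim: int = 3, phi0: float = 0.30,
                         growth0: float = 0.03, sweeps: int = 80,
                         growth_min: float = 2e-4, shrink: float = 0.7,
                         max_events: int = 4000) -> tuple[np.ndarray, float]:
    """Densify ``n`` equal spheres (or disks, ``dim=2``) in a periodic unit box.

    Returns ``(centers, packing_fraction)`` with centers in box units and the
    sphere radius implied by ``packing_fraction``.  Radii grow until the
    growth rate stalls (the packing jams); for 3D this terminates near the
    random-close-packing fraction ~0.64.  Raises :class:`PackingError` if the
    event budget is exhausted before jamming.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), dim, n]))
    pos = rng.random((n, dim))
    if n == 1:
        return pos, phi0
    vel = np.zeros_like(pos)
    cd = 4.0 / 3.0 * np.pi if dim == 3 else np.pi
    r = (phi0 / (n * cd)) ** (1.0 / dim)

    def min_gap_radius():
        tree = cKDTree(pos, boxsize=1.0)
        dd, _ = tree.query(pos, k=2)
        return dd[:, 1].min() / 2.0

    if not _relax(pos, vel, r, 2000, rng):
        raise PackingError(f"initial packing fraction {phi0} not feasible")
    g = growth0
    events = 0
    while g > growth_min:
        events += 1
        if events > max_events:
            raise PackingError(
                f"densification event budget exhausted at packing fraction "
                f"{n * cd * r**dim:.4f}")
        r_try = r * (1 + g)
        ok = _relax(pos, vel, r_try, sweeps, rng)
        if not ok:  # one shake to escape a shallow jam, then retry
            pos += rng.normal(scale=g * r, size=pos.shape)
            np.mod(pos, 1.0, out=pos)
            ok = _relax(pos, vel, r_try, sweeps, rng)
        if ok:
            r = r_try
        else:
            r_in = min_gap_radius() * (1 - 0.1 * OVERLAP_TOL)
            if r_in > r * (1 + 0.05 * g):
                r = min(r_in, r_try)
            else:
                g *= shrink
                r = max(r, r_in)
    return pos, float(n * cd * r**dim)


def _carve(pos, n_keep, dim):
    """Select the n_keep centers nearest the box center; re-center on their
    centroid and return coordinates in box units."""
    ref = np.full(dim, 0.5)
    d = np.linalg.norm(pos - ref, axis=1)
    order = np.argsort(d, kind="stable")[:n_keep]
    sel = pos[order] - ref
    sel -= sel.mean(axis=0)
    return sel


def build_assembly(dist: RadiiDistribution, n: int, *, mode: str = "cluster",
                   target_packing: float | None = None, seed=0,
                   oversample: float = 2.1) -> SpheroidModel:
    """Build a packed cluster or monolayer of ``n`` cells.

    ``target_packing`` is the realized cell-volume fraction (cluster) or
    cell-area fraction (monolayer) inside the bounding sphere/disk; defaults
    are 0.17 for clusters (loosely associated spheroids) and 0.50 for
    monolayers (subconfluent culture).  The monodisperse RCP stage provides
    the disordered center pattern; centers are then rescaled so the realized
    fraction matches the target.
    """
    if mode not in ("cluster", "monolayer"):
        raise ValueError(f"unknown mode {mode!r}")
    dim = 3 if mode == "cluster" else 2
    if target_packing is None:
        target_packing = 0.17 if mode == "cluster" else 0.50
    if n < 1:
        raise ValueError("n must be >= 1")

    m = max(int(np.ceil(oversample * n)), n)
    centers_box, rcp_phi = generate_rcp_centers(m, seed, dim=dim)
    if target_packing >= rcp_phi and n > 1:
        raise PackingError(
            f"target packing {target_packing} is not below the achieved "
            f"RCP density {rcp_phi:.3f}")
    carved = _carve(centers_box, n, dim)
    if dim == 2:
        carved = np.column_stack([carved, np.zeros(n)])

    R_c, R_n = sample_radii(dist, n, np.random.SeedSequence([int(seed), 7]))
    # rank-preserving assignment: roomier sites receive larger cells
    if n > 1:
        tree = cKDTree(carved)
        nn_dist, _ = tree.query(carved, k=2)
        room_rank = np.argsort(np.argsort(nn_dist[:, 1], kind="stable"), kind="stable")
        order = np.argsort(R_c, kind="stable")
        R_c = R_c[order][room_rank]
        R_n = R_n[order][room_rank]

    radial = np.linalg.norm(carved, axis=1)

    def realized(scale):
        rb = np.max(scale * radial + R_c)
        if dim == 3:
            return np.sum(R_c**3) / rb**3, rb
        return np.sum(R_c**2) / rb**2, rb

    if n == 1:
        scale = 1.0
        bounding = float(R_c[0])
        phi = 1.0
    else:
        lo, hi = 1e-6, 1.0
        while realized(hi)[0] > target_packing:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized(mid)[0] > target_packing:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        phi, bounding = realized(scale)

    centers = carved * scale
    model = SpheroidModel(
        centers=centers, R_c=R_c, R_n=R_n, mode=mode, seed=int(seed),
        bounding_radius=float(bounding), packing_fraction=float(phi),
        rcp_packing_fraction=float(rcp_phi))
    _repair_overlaps(model)
    return model


def _repair_overlaps(model: SpheroidModel, max_iter: int = 50) -> None:
    """Nudge apart the rare residual overlapping pairs after radius
    reassignment (dilute packings leave plenty of room)."""
    for _ in range(max_iter):
        bad = _overlap_pairs(model)
        if len(bad) == 0:
            return
        i, j = bad[:, 0].astype(int), bad[:, 1].astype(int)
        d = model.centers[i] - model.centers[j]
        dist = np.linalg.norm(d, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        need = (model.R_c[i] + model.R_c[j]) - dist
        mv = (0.6 * need / dist)[:, None] * d
        np.add.at(model.centers, i, mv)
        np.add.at(model.centers, j, -mv)
    # keep the declared bounding radius valid after nudging
    rb = float(np.max(np.linalg.norm(model.centers, axis=1) + model.R_c))
    model.bounding_radius = max(model.bounding_radius, rb)


def _overlap_pairs(model: SpheroidModel) -> np.ndarray:
    tree = cKDTree(model.centers)
    cut = 2.0 * float(model.R_c.max())
    pairs = tree.query_pairs(cut, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    i, j = pairs[:, 0], pairs[:, 1]
    dist = np.linalg.norm(model.centers[i] - model.centers[j], axis=1)
    gap = dist - (model.R_c[i] + model.R_c[j])
    allowed = -GAP_TOL_FRACTION * np.minimum(model.R_c[i], model.R_c[j])
    return pairs[gap < allowed]


def audit_overlaps(model: SpheroidModel) -> bool:
    """True iff no pair of cells overlaps beyond the hard-core tolerance."""
    return len(_overlap_pairs(model)) == 0


def peripheral_mask(model: SpheroidModel, shell_depth: float) -> np.ndarray:
    """Boolean mask of cells whose center lies within ``shell_depth`` um of
    the bounding radius (the peripheral rim of the spheroid)."""
    if shell_depth <= 0:
        raise ValueError("shell_depth must be positive")
    return model.radial_distance >= model.bounding_radius - shell_depth
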