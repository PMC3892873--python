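"""Floor-plane estimation and plane-relative geometry.

The floor is modelled as a plane Ax + By + Cz + D = 0 with a unit normal
oriented towards the camera's "up" (B >= 0).  It is estimated from a 3D point
cloud by RANSAC followed by a total-least-squares refit of the inliers.  The
plane provides the reference frame for every altitude and balance measure:
the tilt cosine against the camera's vertical axis, perpendicular projection
into a fixed in-plane 2D basis, point-to-plane altitude, and the distance of
the projected body centroid to the base-of-support line through the two feet.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import numpy as np


@dataclass(frozen=True)
class FloorPlane:
    """Normalized floor-plane coefficients.

    (A, B, C) is a unit normal with B >= 0; ``tilt_cos`` is its cosine against
    the camera vertical (0, 1, 0), i.e. exactly B after normalization.
    """

    A: float
    B: float
    C: float
    D: float
    inlier_count: int = 0
    tilt_cos: float = 0.0

    @classmethod
    def from_coefficients(cls, A: float, B: float, C: float, D: float,
                          inlier_count: int = 0) -> "FloorPlane":
        n = np.array([A, B, C], dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("degenerate plane normal")
        n /= norm
        D = float(D) / norm
        if n[1] < 0 or (n[1] == 0 and (n[0] < 0 or (n[0] == 0 and n[2] < 0))):
            n, D = -n, -D
        tilt_cos = float(np.clip(n[1], 0.0, 1.0))
        return cls(float(n[0]), float(n[1]), float(n[2]), D,
                   inlier_count=inlier_count, tilt_cos=tilt_cos)

    @classmethod
    def horizontal(cls, height: float = 0.0) -> "FloorPlane":
        """The plane y = height (an untilted camera over a level floor)."""
        return cls.from_coefficients(0.0, 1.0, 0.0, -height)

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane basis (u, v).

        u is the unit projection of the camera x-axis into the plane (falling
        back to the z-axis if the normal is parallel to x); v completes the
        basis so that a horizontal floor yields (u, v) = (x, z).
        """
        n = self.normal
        x_hat = np.array([1.0, 0.0, 0.0])
        u = x_hat - np.dot(x_hat, n) * n
        if np.linalg.norm(u) < 1e-9:
            z_hat = np.array([0.0, 0.0, 1.0])
            u = z_hat - np.dot(z_hat, n) * n
        u /= np.linalg.norm(u)
        v = np.cross(u, n)
        return u, v


def point_plane_distance(p: np.ndarray, plane: FloorPlane,
                         strict: bool = True) -> Union[float, np.ndarray]:
    """Altitude of point(s) above the floor plane.

    In strict mode the perpendicular distance |n.p + D| is additionally scaled
    by the plane's tilt cosine (the scalar projection of the camera-vertical
    displacement onto the floor normal); ``strict=False`` returns the plain
    perpendicular distance.
    """
    p = np.asarray(p, dtype=float)
    d = np.abs(p @ plane.normal + plane.D)
    if strict:
        d = d * plane.tilt_cos
    return float(d) if d.ndim == 0 else d


def ground_project(p: np.ndarray, plane: FloorPlane) -> np.ndarray:
    """Perpendicular projection of point(s) onto the floor, in (u, v) coords."""
    p = np.asarray(p, dtype=float)
    n = plane.normal
    q = p - np.multiply.outer(p @ n + plane.D, n)
    u, v = plane.basis()
    out = np.stack([q @ u, q @ v], axis=-1)
    return out


def base_of_support_distance(pc: np.ndarray, left_foot: np.ndarray,
                             right_foot: np.ndarray,
                             coincident_tol: float = 0.01) -> float:
    """Distance from the projected centroid to the base-of-support line.

    All inputs are 2D floor coordinates.  The base of support is the line
    through the two projected foot points; when the feet coincide (within
    ``coincident_tol`` metres) the measure degrades to the point-to-point
    distance from the centroid to the foot location.
    """
    pc = np.asarray(pc, dtype=float)
    f1 = np.asarray(left_foot, dtype=float)
    f2 = np.asarray(right_foot, dtype=float)
    span = f2 - f1
    norm = np.linalg.norm(span)
    if norm < coincident_tol:
        return float(np.linalg.norm(pc - 0.5 * (f1 + f2)))
    # perpendicular point-to-line distance, cross-product form
    return float(abs(span[0] * (pc[1] - f1[1]) - span[1] * (pc[0] - f1[0])) / norm)


def _plane_from_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> Optional[np.ndarray]:
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return None
    n = n / norm
    return np.array([n[0], n[1], n[2], -np.dot(n, p0)])


def _tls_refit(points: np.ndarray) -> np.ndarray:
    """Total-least-squares plane through a point set (smallest PCA axis)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    n = vt[-1]
    return np.array([n[0], n[1], n[2], -np.dot(n, c)])


def fit_floor_ransac(cloud: np.ndarray, inlier_tol: float = 0.02,
                     iters: int = 500, seed: int = 0) -> FloorPlane:
    """Robust floor-plane fit: RANSAC hypotheses + TLS refit of the inliers.

    ``cloud`` is an (N, 3) array of metres.  ``iters`` random 3-point
    hypotheses are scored by perpendicular-distance inlier count at
    ``inlier_tol``; the winning consensus set is refit by total least squares.
    """
    points = np.asarray(cloud, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise ValueError("cloud must be (N >= 3, 3)")
    if inlier_tol <= 0:
        raise ValueError("inlier_tol must be positive")
    rng = np.random.default_rng(seed)
    n_pts = points.shape[0]
    best_count = -1
    best_plane: Optional[np.ndarray] = None
    for _ in range(iters):
        idx = rng.choice(n_pts, size=3, replace=False)
        coeffs = _plane_from_points(*points[idx])
        if coeffs is None:
            continue
        dist = np.abs(points @ coeffs[:3] + coeffs[3])
        count = int(np.count_nonzero(dist <= inlier_tol))
        if count > best_count:
            best_count, best_plane = count, coeffs
    if best_plane is None:
        raise ValueError("no plane: all sampled triplets were collinear")
    inliers = np.abs(points @ best_plane[:3] + best_plane[3]) <= inlier_tol
    if inliers.sum() >= 3:
        refit = _tls_refit(points[inliers])
        dist = np.abs(points @ refit[:3] + refit[3])
        best_plane = refit
        best_count = int(np.count_nonzero(dist <= inlier_tol))
    return FloorPlane.from_coefficients(*best_plane, inlier_count=best_count)


def fit_floor_exhaustive(cloud: np.ndarray, inlier_tol: float = 0.02) -> FloorPlane:
    """Brute-force best 3-point plane (for small clouds); no refit.

    The reference against which the randomized fit is checked on tiny inputs.
    """
    points = np.asarray(cloud, dtype=float)
    best_count, best_plane = -1, None
    for idx in combinations(range(points.shape[0]), 3):
        coeffs = _plane_from_points(*points[list(idx)])
        if coeffs is None:
            continue
        dist = np.abs(points @ coeffs[:3] + coeffs[3])
        count = int(np.count_nonzero(dist <= inlier_tol))
        if count > best_count:
            best_count, best_plane = count, coeffs
    if best_plane is None:
        raise ValueError("no plane: all point triplets collinear")
    return FloorPlane.from_coefficients(*best_plane, inlier_count=best_count)


# ---------------------------------------------------------------------------
# Point-cloud I/O: xyz CSV and ASCII PLY
# ---------------------------------------------------------------------------

def write_cloud_csv(points: np.ndarray, path: Union[str, Path]) -> None:
    points = np.asarray(points, dtype=float)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z"])
        for x, y, z in points:
            writer.writerow([f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])


def read_cloud_csv(path: Union[str, Path]) -> np.ndarray:
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        pts = [(float(r["x"]), float(r["y"]), float(r["z"])) for r in reader]
    return np.asarray(pts, dtype=float)


def write_cloud_ply(points: np.ndarray, path: Union[str, Path]) -> None:
    points = np.asarray(points, dtype=float)
    with Path(path).open("w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {points.shape[0]}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_cloud_ply(path: Union[str, Path]) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    try:
        start = lines.index("end_header") + 1
    except ValueError as exc:
        raise ValueError("not an ASCII PLY file") from exc
    n_vertex = 0
    for line in lines[:start]:
        if line.startswith("element vertex"):
            n_vertex = int(line.split()[-1])
        if line.startswith("format") and "ascii" not in line:
            raise ValueError("only ASCII PLY is supported")
    pts = [tuple(map(float, line.split()[:3])) for line in lines[start:start + n_vertex]]
    return np.asarray(pts, dtype=float)


def read_cloud(path: Union[str, Path]) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".csv":
        return read_cloud_csv(path)
    if path.suffix == ".ply":
        return read_cloud_ply(path)
    raise ValueError(f"unknown cloud format: {path.suffix}")
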