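"""Occupancy, hydration-site clustering and bulk-density analysis.

Hydration sites are identified by pooling primary-site (water oxygen)
positions over frames and cutting an average-linkage hierarchical
clustering dendrogram at a 2.4 Å distance cutoff.  Cluster locations are
compared against reference (e.g. crystallographic) sites with a 1.4 Å
match threshold — the van der Waals radius of a water molecule.  Occupancy
is reported both as the fraction of frames contributing at least one
member to the cluster and as mean members per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .constants import AVOGADRO
from .driver import Frame
from .errors import DomainError
from .grand_moves import GCRegion
from .model import minimum_image

CLUSTER_CUTOFF = 2.4  # Å, average-linkage dendrogram cut
MATCH_THRESHOLD = 1.4  # Å, agreement with a reference site


def occupancy_histogram(frames: list[Frame], region: GCRegion | None = None) -> dict[int, float]:
    """Normalized distribution of the number of region members per frame."""
    if not frames:
        raise DomainError("at least one frame is required")
    counts = np.array([f.region_count for f in frames])
    values, freq = np.unique(counts, return_counts=True)
    return {int(v): float(c) / len(frames) for v, c in zip(values, freq)}


@dataclass
class HydrationSite:
    position: np.ndarray  # centroid, Å
    occupancy: float  # fraction of frames contributing >= 1 member
    mean_members_per_frame: float
    member_count: int


@dataclass
class ClusterReport:
    sites: list[HydrationSite] = field(default_factory=list)
    #: (site index, reference index, distance Å) for matched pairs
    reference_matches: list[tuple[int, int, float]] = field(default_factory=list)
    n_frames: int = 0


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).  Returns (R, t) such that
    ``mobile @ R.T + t`` best fits ``reference``."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def align_frames(frames: list[Frame]) -> list[np.ndarray]:
    """Primary-site positions per frame, superposed on the first frame's
    alignment reference sites when available (rigid scaffolds superpose to
    the identity)."""
    out = []
    ref = frames[0].align_positions if frames and frames[0].align_positions is not None else None
    for f in frames:
        pos = np.asarray(f.primary_positions, dtype=float).reshape(-1, 3)
        if ref is not None and f.align_positions is not None and len(ref) >= 3:
            R, t = superpose(np.asarray(f.align_positions), np.asarray(ref))
            pos = pos @ R.T + t
        out.append(pos)
    return out


def cluster_hydration_sites(frames: list[Frame], cutoff: float = CLUSTER_CUTOFF,
                            align: bool = True) -> ClusterReport:
    """Average-linkage clustering of pooled primary-site positions.

    Flat clusters are cut from the dendrogram at ``cutoff``; the reported
    site is the cluster centroid.  Occupancy = frames with >= 1 member /
    total frames.
    """
    n_frames = len(frames)
    per_frame = align_frames(frames) if align else [
        np.asarray(f.primary_positions, dtype=float).reshape(-1, 3) for f in frames]
    frame_of = np.concatenate([
        np.full(len(p), i) for i, p in enumerate(per_frame)]) if per_frame else np.zeros(0)
    pooled = np.vstack(per_frame) if per_frame else np.zeros((0, 3))
    report = ClusterReport(n_frames=n_frames)
    if len(pooled) == 0:
        return report
    if len(pooled) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pooled, method="average")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    for lab in np.unique(labels):
        sel = labels == lab
        members = pooled[sel]
        contributing = len(np.unique(frame_of[sel]))
        report.sites.append(HydrationSite(
            position=members.mean(axis=0),
            occupancy=contributing / n_frames,
            mean_members_per_frame=float(np.count_nonzero(sel)) / n_frames,
            member_count=int(np.count_nonzero(sel)),
        ))
    report.sites.sort(key=lambda s: -s.occupancy)
    return report


def match_to_reference(report: ClusterReport, reference: np.ndarray,
                       threshold: float = MATCH_THRESHOLD) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of cluster sites to reference coordinates
    by ascending distance; only pairs closer than ``threshold`` match."""
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if not report.sites or len(reference) == 0:
        report.reference_matches = []
        return []
    sites = np.array([s.position for s in report.sites])
    dist = cdist(sites, reference)
    pairs = sorted(
        ((dist[i, j], i, j) for i in range(dist.shape[0]) for j in range(dist.shape[1])),
    )
    used_sites: set[int] = set()
    used_refs: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if d >= threshold:
            break
        if i in used_sites or j in used_refs:
            continue
        matches.append((i, j, float(d)))
        used_sites.add(i)
        used_refs.add(j)
    report.reference_matches = matches
    return matches


def bulk_density(frames: list[Frame], molecule_mass: float) -> float:
    """Mean mass density over frames, g/cm³, for a whole-box solvent system.

    ``molecule_mass`` is the mass of one movable molecule in amu; each
    frame's density is n_molecules · mass / (N_A · V).
    """
    if not frames:
        return 0.0
    dens = []
    for f in frames:
        n = len(np.asarray(f.primary_positions).reshape(-1, 3))
        vol_cm3 = float(np.prod(f.box)) * 1e-24
        dens.append(n * molecule_mass / (AVOGADRO * vol_cm3))
    return float(np.mean(dens))
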