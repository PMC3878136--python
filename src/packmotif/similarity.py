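"""Cross-structure packing comparison and supramolecular-construct detection.

The comparison of two crystal structures is purely geometric.  Around a kernel
molecule of each structure a coordination-sphere cluster is built; every
kernel->neighbour relationship is condensed into a rigid-motion-invariant
descriptor (centroid distance, relative orientation as a quaternion in the
kernel's molecular frame, direction of the centroid offset in that frame, and a
proper/improper parity bit).  Descriptors of the two clusters are then matched
one-to-one within user tolerances; the matched neighbours that are related to the
kernel by pure lattice translation in *both* structures span a translation
sublattice whose rank is the dimensionality of the shared motif:

    0 -> a discrete assembly (e.g. an H-bonded dimer),
    1 -> a common row / stack / tape with one base vector,
    2 -> a common layer,
    3 -> isostructural packing.

Family-wide comparison merges congruent pairwise motifs into named supramolecular
constructs (SCs): family letter + dimensionality digit + ordinal (A01, A11, B11,
...), with base vectors labelled t1, t2, ... in order of first appearance and
sub-construct dependencies derived from descriptor-set containment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .clusters import Cluster, build_cluster
from .crystal_model import CrystalStructure, Molecule
from .errors import CorrespondenceError, GeometryError

__all__ = [
    "CorrespondenceSet",
    "MatchTolerances",
    "PairDescriptor",
    "MatchedPair",
    "MatchResult",
    "SupramolecularConstruct",
    "FamilyResult",
    "make_correspondence",
    "pair_descriptor",
    "cluster_descriptors",
    "match_clusters",
    "derive_dimensionality",
    "dissimilarity_index",
    "compare_family",
    "compare_pair",
]

_FORBIDDEN = 1e9


# ------------------------------------------------------------------ correspondence

@dataclass(frozen=True)
class CorrespondenceSet:
    """Ordered non-hydrogen atom labels matched one-to-one across structures."""

    labels: tuple[str, ...]

    def __len__(self):
        return len(self.labels)


def _host_labels(structure: CrystalStructure) -> set[str]:
    host = structure.host()
    return {l for l, e in zip(host.labels, host.elements) if e != "H"}


def _check_non_collinear(points: np.ndarray, what: str):
    if len(points) < 3:
        raise CorrespondenceError(f"{what}: fewer than 3 points")
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-6 * max(1.0, s[0]):
        raise CorrespondenceError(f"{what}: points are collinear")


def make_correspondence(*structures: CrystalStructure,
                        selection="auto") -> CorrespondenceSet:
    """Common non-H atom labels of the host molecules, ordered lexicographically.

    ``selection="auto"`` intersects the label sets of all given structures;
    an explicit label list overrides.  At least three non-collinear points are
    required.
    """
    if selection == "auto":
        common = _host_labels(structures[0])
        for s in structures[1:]:
            common &= _host_labels(s)
        labels = tuple(sorted(common))
    else:
        labels = tuple(selection)
    if len(labels) < 3:
        raise CorrespondenceError(
            f"only {len(labels)} shared labels between "
            f"{[s.structure_id for s in structures]}")
    pts = structures[0].host().subset_coords(labels)
    _check_non_collinear(pts, "correspondence")
    return CorrespondenceSet(labels)


# ------------------------------------------------------------------ descriptors

@dataclass(frozen=True)
class PairDescriptor:
    """Rigid-motion-invariant kernel->neighbour relationship.

    ``d``: centroid distance of the correspondence point sets (Angstrom);
    ``quat``: unit quaternion (x, y, z, w) of the best proper superposition,
    expressed in the kernel's local orthonormal frame; ``u``: unit centroid-offset
    direction in the same frame; ``proper``: False when the neighbour is related by
    an improper (inversion/mirror) operation.
    """

    d: float
    quat: tuple[float, float, float, float]
    u: tuple[float, float, float]
    proper: bool

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)


def _local_frame(points: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame (columns) from >= 3 non-collinear points.

    Principal axes of the centred point set (all points contribute, so the
    frame is robust to per-atom coordinate noise), with signs fixed by the
    skewness of the projections on each axis (an aggregate, hence equally
    noise-robust, statistic; the point of largest projection breaks a
    near-symmetric tie) and a right-handed third axis.  Assumes the two
    leading principal moments are non-degenerate, which holds for the
    elongated planar molecules this pipeline targets.
    """
    pts = np.asarray(points, dtype=float)
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-6 * max(s[0], 1.0):
        raise GeometryError("degenerate correspondence frame: points collinear")
    axes = [vt[0], vt[1]]
    for k, e in enumerate(axes):
        proj = centred @ e
        skew = float(np.sum(proj ** 3))
        if abs(skew) > 1e-3 * max(s[0], 1.0) ** 3 / len(pts):
            flip = skew < 0
        else:
            flip = proj[int(np.argmax(np.abs(proj)))] < 0
        if flip:
            axes[k] = -e
    e1, e2 = axes
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _kabsch(moving: np.ndarray, target: np.ndarray):
    """Best rigid superposition of ``moving`` onto ``target``.

    Returns ``(R, proper)``: if the optimal alignment is improper, ``R`` is the
    best proper rotation aligning the *inverted* moving set and ``proper`` is
    False.
    """
    A = target - target.mean(axis=0)
    B = moving - moving.mean(axis=0)
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    proper = bool(np.linalg.det(U @ Vt) > 0)
    if not proper:
        B = -B
        H = B.T @ A
        U, S, Vt = np.linalg.svd(H)
        if np.linalg.det(U @ Vt) < 0:  # numerically degenerate (planar) set
            Vt = Vt.copy()
            Vt[2] *= -1
        R = (U @ Vt).T
    else:
        R = (U @ Vt).T
    return R, proper


def _gauged_frame(points: np.ndarray, ref_points: np.ndarray,
                  ref_frame: np.ndarray) -> np.ndarray:
    """Local frame of ``points`` made sign-consistent with a reference frame.

    Principal axes are defined only up to sign; noise can flip them between
    otherwise matching structures.  The frame is transported onto the reference
    by the best proper superposition and snapped to the nearest proper sign
    flip, which removes the ambiguity deterministically.
    """
    frame = _local_frame(points)
    rot, _ = _kabsch(points, ref_points)
    m = ref_frame.T @ rot @ frame
    signs = np.sign(np.diag(m))
    signs[signs == 0] = 1.0
    if np.prod(signs) < 0:  # enantiomeric or degenerate; restore handedness
        signs[int(np.argmin(np.abs(np.diag(m))))] *= -1
    return frame @ np.diag(signs)


def pair_descriptor(cluster: Cluster, shell_index: int,
                    correspondence: CorrespondenceSet,
                    frame: np.ndarray | None = None) -> PairDescriptor:
    """Descriptor of one kernel->shell-member relationship."""
    return _descriptor(cluster.kernel, cluster.shell[shell_index],
                       correspondence, frame)


def _descriptor(kernel: Molecule, neighbour: Molecule,
                correspondence: CorrespondenceSet,
                frame: np.ndarray | None = None) -> PairDescriptor | None:
    try:
        pk = kernel.subset_coords(correspondence.labels)
        pn = neighbour.subset_coords(correspondence.labels)
    except KeyError:
        return None  # neighbour (e.g. water) does not carry the correspondence
    if frame is None:
        frame = _local_frame(pk)
    ck, cn = pk.mean(axis=0), pn.mean(axis=0)
    offset = cn - ck
    d = float(np.linalg.norm(offset))
    R, proper = _kabsch(pn, pk)
    R_local = frame.T @ R @ frame
    quat = Rotation.from_matrix(R_local).as_quat()
    if d > 1e-9:
        u = frame.T @ (offset / d)
    else:
        u = np.array([0.0, 0.0, 1.0])
    return PairDescriptor(d=d, quat=tuple(float(x) for x in quat),
                          u=tuple(float(x) for x in u), proper=proper)


def cluster_descriptors(cluster: Cluster, correspondence: CorrespondenceSet,
                        frame: np.ndarray | None = None):
    """Descriptors for every shell member (None where not applicable)."""
    return [_descriptor(cluster.kernel, m, correspondence, frame)
            for m in cluster.shell]


# ------------------------------------------------------------------ matching

@dataclass(frozen=True)
class MatchTolerances:
    """Acceptance tolerances: ``d`` absolute distance (Angstrom), ``ang`` degrees
    for both the quaternion angular distance and the offset-direction angle."""

    d: float = 0.5
    ang: float = 12.0


@dataclass(frozen=True)
class MatchedPair:
    index_a: int
    index_b: int
    dev_d: float
    dev_rot: float
    dev_u: float

    def score(self, tol: MatchTolerances) -> float:
        return math.sqrt(((self.dev_d / tol.d) ** 2 + (self.dev_rot / tol.ang) ** 2
                          + (self.dev_u / tol.ang) ** 2) / 3.0)


@dataclass
class MatchResult:
    cluster_a: Cluster
    cluster_b: Cluster
    correspondence: CorrespondenceSet
    tolerances: MatchTolerances
    pairs: list[MatchedPair]
    descriptors_a: list
    descriptors_b: list
    frame_a: np.ndarray | None = None
    frame_b: np.ndarray | None = None

    def __len__(self):
        return len(self.pairs)


def _deviation(da: PairDescriptor, db: PairDescriptor):
    dev_d = abs(da.d - db.d)
    dev_rot = math.degrees((da.rotation.inv() * db.rotation).magnitude())
    cu = float(np.clip(np.dot(da.u, db.u), -1.0, 1.0))
    dev_u = math.degrees(math.acos(cu))
    return dev_d, dev_rot, dev_u


def match_clusters(cluster_a: Cluster, cluster_b: Cluster,
                   correspondence: CorrespondenceSet,
                   tol: MatchTolerances = MatchTolerances(),
                   frame_a: np.ndarray | None = None,
                   frame_b: np.ndarray | None = None) -> MatchResult:
    """One-to-one assignment of shell members with congruent descriptors.

    A pair is admissible when parities agree, |d_A - d_B| <= tol.d and both
    angular deviations are <= tol.ang.  Among admissible pairs a deterministic
    minimum-cost assignment (normalized rms deviation) of maximal cardinality is
    returned.  Kernel frames may be supplied (e.g. gauged family-wide by
    :func:`compare_family`); by default B's frame is sign-gauged against A's.
    """
    pts_a = cluster_a.kernel.subset_coords(correspondence.labels)
    pts_b = cluster_b.kernel.subset_coords(correspondence.labels)
    if frame_a is None:
        frame_a = _local_frame(pts_a)
    if frame_b is None:
        frame_b = _gauged_frame(pts_b, pts_a, frame_a)
    des_a = cluster_descriptors(cluster_a, correspondence, frame_a)
    des_b = cluster_descriptors(cluster_b, correspondence, frame_b)
    ia = [i for i, d in enumerate(des_a) if d is not None]
    ib = [j for j, d in enumerate(des_b) if d is not None]
    pairs: list[MatchedPair] = []
    if ia and ib:
        cost = np.full((len(ia), len(ib)), _FORBIDDEN)
        devs = {}
        for x, i in enumerate(ia):
            for y, j in enumerate(ib):
                da, db = des_a[i], des_b[j]
                if da.proper != db.proper:
                    continue
                dev_d, dev_rot, dev_u = _deviation(da, db)
                if dev_d <= tol.d and dev_rot <= tol.ang and dev_u <= tol.ang:
                    mp = MatchedPair(i, j, dev_d, dev_rot, dev_u)
                    cost[x, y] = mp.score(tol)
                    devs[(x, y)] = mp
        rows, cols = linear_sum_assignment(cost)
        for x, y in zip(rows, cols):
            if cost[x, y] < _FORBIDDEN:
                pairs.append(devs[(x, y)])
        pairs.sort(key=lambda p: (p.index_a, p.index_b))
    return MatchResult(cluster_a, cluster_b, correspondence, tol, pairs,
                       des_a, des_b, frame_a, frame_b)


def dissimilarity_index(match: MatchResult) -> float:
    """Root-mean-square of tolerance-normalized deviations over matched pairs.

    0 for exact self-comparison; <= 1 for any accepted match set.  Raises
    ``ValueError`` on an empty match.
    """
    if not match.pairs:
        raise ValueError("dissimilarity index undefined for an empty match")
    tol = match.tolerances
    vals = []
    for p in match.pairs:
        vals.extend([(p.dev_d / tol.d) ** 2, (p.dev_rot / tol.ang) ** 2,
                     (p.dev_u / tol.ang) ** 2])
    return math.sqrt(sum(vals) / len(vals))


# ------------------------------------------------------------------ dimensionality

def _pure_translation_vector(cluster: Cluster, shell_index: int) -> np.ndarray | None:
    """Cartesian lattice vector when the member is a pure translation of the kernel."""
    m = cluster.shell[shell_index]
    prov = m.provenance
    if prov.mol_index != cluster.kernel.provenance.mol_index:
        return None
    op = cluster.structure.operators[prov.op_index]
    if not op.is_pure_translation:
        return None
    frac = op.tran_array + np.array(prov.shift, dtype=float)
    return cluster.structure.ortho @ frac


def derive_dimensionality(match: MatchResult):
    """Dimensionality and base vectors of a matched motif.

    The translation sublattice of the shared motif is generated two ways: (i)
    matched shell members related to their kernels by pure lattice translation in
    *both* structures, and (ii) lattice-offset differences between matched members
    generated by the same operator in each structure -- e.g. the inversion
    partners of consecutive dimers along a tape, which carry the tape repeat even
    when the repeat itself exceeds the molecular contact range.  A difference is
    accepted only when its vector agrees between the two structures (magnitude
    within tol.d, direction in the kernel frames within tol.ang).  The rank of
    the sublattice is the dimensionality; a shortest generating set gives the
    base vectors (reported for both structures, index-aligned).  Rank 0 with at
    least one matched symmetry-related member is 0D (discrete-assembly)
    similarity.

    Returns ``(dim, base_a, base_b)`` with base vectors as Cartesian arrays.
    """
    if not match.pairs:
        raise ValueError("cannot derive dimensionality of an empty match")
    tol = match.tolerances
    frame_a = match.frame_a
    frame_b = match.frame_b
    trans_a, trans_b = [], []
    # (i) pure translations
    for p in match.pairs:
        va = _pure_translation_vector(match.cluster_a, p.index_a)
        vb = _pure_translation_vector(match.cluster_b, p.index_b)
        if va is not None and vb is not None:
            trans_a.append(va)
            trans_b.append(vb)
    # (ii) offset differences within operator classes
    groups: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
    kern_a = match.cluster_a.kernel.provenance.mol_index
    kern_b = match.cluster_b.kernel.provenance.mol_index
    for p in match.pairs:
        pa = match.cluster_a.shell[p.index_a].provenance
        pb = match.cluster_b.shell[p.index_b].provenance
        if pa.mol_index != kern_a or pb.mol_index != kern_b:
            continue
        la = _lattice_offset(match.cluster_a, p.index_a)
        lb = _lattice_offset(match.cluster_b, p.index_b)
        groups.setdefault((pa.op_index, pb.op_index), []).append((la, lb))
    for members in groups.values():
        for (la1, lb1), (la2, lb2) in itertools.combinations(members, 2):
            va, vb = la2 - la1, lb2 - lb1
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na < 1e-6 or abs(na - nb) > tol.d:
                continue
            ua, ub = frame_a.T @ (va / na), frame_b.T @ (vb / nb)
            ang = math.degrees(math.acos(np.clip(float(ua @ ub), -1.0, 1.0)))
            if ang <= tol.ang:
                trans_a.append(va)
                trans_b.append(vb)
    if not trans_a:
        return 0, [], []
    return _consistent_sublattice(trans_a, trans_b, tol.d)


def _consistent_sublattice(trans_a, trans_b, tol_d):
    """Greedy shortest basis of the matched translation pairs, with closure.

    A candidate pair extends the basis only if every small integer combination
    of the extended basis has the same length in both structures (within
    ``tol_d``): this rejects tolerance artifacts where a long combination
    vector happens to match although its short constituents do not.
    Candidates are ranked by how well their lengths agree across the two
    structures (in tol_d/10 buckets) before length, so an exactly shared
    repeat beats a shorter combination that only matches coincidentally.
    """
    bucket = max(tol_d / 10.0, 1e-9)

    def rank(i):
        dev = abs(float(np.linalg.norm(trans_a[i]) - np.linalg.norm(trans_b[i])))
        return (int(round(dev / bucket)),
                round(float(np.linalg.norm(trans_a[i])), 9),
                tuple(np.round(trans_a[i], 6)))

    order = sorted(range(len(trans_a)), key=rank)
    basis_a: list[np.ndarray] = []
    basis_b: list[np.ndarray] = []
    for i in order:
        va, vb = trans_a[i], trans_b[i]
        if np.linalg.norm(va) < 1e-6:
            continue
        trial_a = basis_a + [va]
        if np.linalg.matrix_rank(np.array(trial_a), tol=1e-4) != len(trial_a):
            continue
        trial_b = basis_b + [vb]
        ok = True
        for coeffs in itertools.product((-1, 0, 1), repeat=len(trial_a)):
            ca = sum(c * v for c, v in zip(coeffs, trial_a))
            cb = sum(c * v for c, v in zip(coeffs, trial_b))
            if abs(np.linalg.norm(ca) - np.linalg.norm(cb)) > tol_d:
                ok = False
                break
        if ok:
            basis_a, basis_b = trial_a, trial_b
        if len(basis_a) == 3:
            break
    return len(basis_a), basis_a, basis_b


# ------------------------------------------------------------------ pairwise motifs

@dataclass(frozen=True)
class SigItem:
    """One matched kernel->neighbour relationship of a motif signature.

    ``offset`` is the neighbour's lattice offset expressed in the reference
    kernel's local frame (None when unavailable); ``translation`` marks pure
    lattice-translation members.
    """

    desc: PairDescriptor
    offset: tuple | None
    translation: bool


@dataclass
class _Motif:
    """A shared packing motif found between one ordered pair of structures."""

    members: tuple[str, str]  # (reference id, other id); reference first in input order
    dim: int
    signature: list[SigItem]          # items on the reference side
    base_local: list[np.ndarray]      # base vectors in the reference kernel frame
    base_mags: list[list[float]]      # per base vector: magnitudes on both sides
    order: tuple                      # deterministic processing key
    implied: bool = False


def compare_pair(struct_a: CrystalStructure, struct_b: CrystalStructure,
                 correspondence: CorrespondenceSet | None = None,
                 tol: MatchTolerances = MatchTolerances(),
                 margin: float = 1.5):
    """Convenience wrapper: clusters, match, dimensionality for two structures.

    Returns ``(match, dim, base_a, base_b)``; ``dim`` is None when nothing matches.
    """
    if correspondence is None:
        correspondence = make_correspondence(struct_a, struct_b)
    ca = build_cluster(struct_a, margin=margin)
    cb = build_cluster(struct_b, margin=margin)
    match = match_clusters(ca, cb, correspondence, tol)
    if not match.pairs:
        return match, None, [], []
    dim, base_a, base_b = derive_dimensionality(match)
    return match, dim, base_a, base_b


def _kernel_frame(cluster: Cluster, correspondence: CorrespondenceSet) -> np.ndarray:
    return _local_frame(cluster.kernel.subset_coords(correspondence.labels))


def _lattice_offset(cluster: Cluster, shell_index: int) -> np.ndarray | None:
    """Cartesian lattice part (op translation + shift) of a shell member."""
    prov = cluster.shell[shell_index].provenance
    if prov.mol_index != cluster.kernel.provenance.mol_index:
        return None
    op = cluster.structure.operators[prov.op_index]
    frac = op.tran_array + np.array(prov.shift, dtype=float)
    return cluster.structure.ortho @ frac


def _direct_motif(match: MatchResult, dim, base_a, base_b,
                  ids: tuple[str, str], order_key) -> "_Motif":
    """The maximal shared motif of one structure pair, with a full signature."""
    frame = match.frame_a
    base_local = [frame.T @ v for v in base_a]
    mags = [[float(np.linalg.norm(v)), float(np.linalg.norm(w))]
            for v, w in zip(base_a, base_b)]
    sig = []
    for p in match.pairs:
        off = _lattice_offset(match.cluster_a, p.index_a)
        va = _pure_translation_vector(match.cluster_a, p.index_a)
        vb = _pure_translation_vector(match.cluster_b, p.index_b)
        sig.append(SigItem(match.descriptors_a[p.index_a],
                           tuple(frame.T @ off) if off is not None else None,
                           va is not None and vb is not None))
    return _Motif(ids, dim, sig, base_local, mags, order_key + (dim,))


def _implied_submotifs(motif: "_Motif", want_0d: bool, want_1d: bool,
                       tol: MatchTolerances) -> list["_Motif"]:
    """Lower-dimensional sub-motifs a motif implies.

    Used as a fallback when a family provides no *direct* evidence for the 0D
    core or the 1D stack a higher-dimensional motif is built from (e.g. a family
    of just two isostructural structures).  The 0D core is the closest matched
    symmetry-related (non-translation) pair; the 1D sub-motif collects members
    whose lattice offsets lie on the line of the shortest base vector.
    """
    out = []
    nontrans = [it for it in motif.signature if not it.translation]
    core = min(nontrans, key=lambda it: it.desc.d) if nontrans else None
    sig1: list[SigItem] = []
    if motif.dim >= 2 and motif.base_local:
        t = np.array(motif.base_local[0])
        tn = t / np.linalg.norm(t)
        # symmetry-related offsets carry an arbitrary wrap constant, so their
        # position on the base-vector line is judged relative to the core
        ref = np.array(core.offset) if core is not None and core.offset else None
        for it in motif.signature:
            if it.offset is None:
                continue
            off = np.array(it.offset)
            if not it.translation and ref is not None:
                off = off - ref
            if np.linalg.norm(off - (off @ tn) * tn) <= tol.d:
                sig1.append(it)
    if want_0d and motif.dim >= 1 and core is not None:
        out.append(_Motif(motif.members, 0, [core], [], [],
                          motif.order + (0,), implied=True))
    if want_1d and sig1:
        out.append(_Motif(motif.members, 1, sig1, [np.array(motif.base_local[0])],
                          [list(motif.base_mags[0])],
                          motif.order + (1,), implied=True))
    return out


def _sig_embed(sig_small, sig_big, tol: MatchTolerances,
               bijective: bool = False) -> bool:
    """Injective (or bijective) embedding of one signature into another.

    Items must match descriptor-wise within tolerance *and* relationally: the
    lattice-offset difference between any two embedded items must have the same
    length and (kernel-frame) direction in both signatures.  The relational test
    rejects tolerance artifacts where individual descriptors agree but the
    motifs' internal periodicities do not.
    """
    if bijective and len(sig_small) != len(sig_big):
        return False
    if len(sig_small) > len(sig_big):
        return False
    cost = np.full((len(sig_small), len(sig_big)), _FORBIDDEN)
    for i, x in enumerate(sig_small):
        for j, y in enumerate(sig_big):
            if x.desc.proper != y.desc.proper:
                continue
            dev_d, dev_rot, dev_u = _deviation(x.desc, y.desc)
            if dev_d <= tol.d and dev_rot <= tol.ang and dev_u <= tol.ang:
                cost[i, j] = dev_d / tol.d + dev_rot / tol.ang + dev_u / tol.ang
    rows, cols = linear_sum_assignment(cost)
    pairs = [(i, j) for i, j in zip(rows, cols) if cost[i, j] < _FORBIDDEN]
    if len(pairs) != len(sig_small):
        return False
    for (i1, j1), (i2, j2) in itertools.combinations(pairs, 2):
        # symmetry-related offsets include an arbitrary per-structure wrap
        # constant; only differences within one operator class (same parity and
        # same relative orientation) are wrap-invariant
        da1, da2 = sig_small[i1].desc, sig_small[i2].desc
        if da1.proper != da2.proper:
            continue
        rot_gap = math.degrees((da1.rotation.inv() * da2.rotation).magnitude())
        if rot_gap > tol.ang:
            continue
        o1a, o2a = sig_small[i1].offset, sig_small[i2].offset
        o1b, o2b = sig_big[j1].offset, sig_big[j2].offset
        if o1a is None or o2a is None or o1b is None or o2b is None:
            continue
        dx = np.array(o2a) - np.array(o1a)
        dy = np.array(o2b) - np.array(o1b)
        nx, ny = np.linalg.norm(dx), np.linalg.norm(dy)
        if abs(nx - ny) > tol.d:
            return False
        if nx > 1e-6 and ny > 1e-6:
            ang = math.degrees(math.acos(np.clip(float(dx @ dy) / (nx * ny),
                                                 -1.0, 1.0)))
            if ang > tol.ang:
                return False
    return True


# ------------------------------------------------------------------ constructs

@dataclass
class SupramolecularConstruct:
    """A packing motif shared by at least two structures of a family."""

    sc_id: str
    dimensionality: int
    members: list[str]
    base_vector_labels: list[str]
    base_magnitude_ranges: list[tuple[float, float]]
    sub_constructs: list[str]      # all contained SCs (full containment)
    dependencies: list[str]        # covering relations only (paper-table style)
    description: str
    signature: list[PairDescriptor] = field(repr=False, default_factory=list)
    base_local: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_structures(self) -> int:
        return len(self.members)


@dataclass
class FamilyResult:
    """Outcome of a family-wide comparison."""

    structure_ids: list[str]
    constructs: list[SupramolecularConstruct]
    tolerances: MatchTolerances
    pairwise: dict  # (id_a, id_b) -> dict(dim=..., n_matched=..., index=...)

    def construct(self, sc_id: str) -> SupramolecularConstruct:
        for sc in self.constructs:
            if sc.sc_id == sc_id:
                return sc
        raise KeyError(sc_id)

    def summary_table(self):
        """Table-style summary, one row per SC (pandas DataFrame)."""
        import pandas as pd

        rows = []
        for sc in self.constructs:
            rows.append({
                "sc_id": sc.sc_id,
                "D": sc.dimensionality,
                "description": sc.description,
                "n_structures": sc.n_structures,
                "members": " ".join(sc.members),
                "base_vectors": " ".join(sc.base_vector_labels),
                "base_magnitudes": " ".join(
                    f"{lo:.3f}-{hi:.3f}" for lo, hi in sc.base_magnitude_ranges),
                "dependencies": " ".join(f"{sc.sc_id}->{d}" for d in sc.dependencies)
                                 or "Primary SC",
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "structures": self.structure_ids,
            "tolerances": {"d": self.tolerances.d, "ang": self.tolerances.ang},
            "constructs": [
                {
                    "sc_id": sc.sc_id,
                    "dimensionality": sc.dimensionality,
                    "members": sc.members,
                    "base_vectors": sc.base_vector_labels,
                    "base_magnitude_ranges": [list(r) for r in sc.base_magnitude_ranges],
                    "sub_constructs": sc.sub_constructs,
                    "dependencies": sc.dependencies,
                    "description": sc.description,
                }
                for sc in self.constructs
            ],
            "pairwise": {f"{a}|{b}": v for (a, b), v in self.pairwise.items()},
        }


def compare_family(structures, selection="auto",
                   tol: MatchTolerances = MatchTolerances(),
                   margin: float = 1.5, include_waters: bool = True) -> FamilyResult:
    """Pairwise comparison of a structure family and SC extraction.

    All pairwise matches are computed with one family-wide correspondence; motifs
    congruent across pairs (checked against the first-discovered reference
    signature) are merged into supramolecular constructs, which are then named,
    given base-vector labels and linked by containment.
    """
    ids = [s.structure_id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate structure ids in family: {ids}")
    if len(structures) < 2:
        return FamilyResult(ids, [], tol, {})
    correspondence = make_correspondence(*structures, selection=selection)
    clusters = {s.structure_id: build_cluster(s, margin=margin,
                                              include_waters=include_waters)
                for s in structures}
    # family-wide frame gauge: every kernel frame is sign-snapped against the
    # first structure so descriptors and signatures are comparable throughout
    ref_pts = clusters[ids[0]].kernel.subset_coords(correspondence.labels)
    ref_frame = _local_frame(ref_pts)
    frames = {ids[0]: ref_frame}
    for sid in ids[1:]:
        pts = clusters[sid].kernel.subset_coords(correspondence.labels)
        frames[sid] = _gauged_frame(pts, ref_pts, ref_frame)
    motifs: list[_Motif] = []
    pairwise = {}
    for (i, sa), (j, sb) in itertools.combinations(enumerate(structures), 2):
        match = match_clusters(clusters[sa.structure_id], clusters[sb.structure_id],
                               correspondence, tol,
                               frame_a=frames[sa.structure_id],
                               frame_b=frames[sb.structure_id])
        if not match.pairs:
            pairwise[(sa.structure_id, sb.structure_id)] = {
                "dim": None, "n_matched": 0, "index": None}
            continue
        dim, base_a, base_b = derive_dimensionality(match)
        pairwise[(sa.structure_id, sb.structure_id)] = {
            "dim": dim, "n_matched": len(match.pairs),
            "index": dissimilarity_index(match)}
        motifs.append(_direct_motif(match, dim, base_a, base_b,
                                    (sa.structure_id, sb.structure_id), (i, j)))

    # ---- merge congruent motifs into SCs (reference = first member by input order)
    motifs.sort(key=lambda m: m.order)

    def merge(motif_list, groups):
        for m in motif_list:
            for g in groups:
                if g["dim"] == m.dim and _sig_embed(g["signature"], m.signature,
                                                    tol, bijective=True):
                    g["members"].update(m.members)
                    for k, mags in enumerate(m.base_mags):
                        g["mags"][k].extend(mags)
                    break
            else:
                groups.append({
                    "dim": m.dim,
                    "signature": m.signature,
                    "base_local": m.base_local,
                    "mags": [list(x) for x in m.base_mags],
                    "members": set(m.members),
                })
        return groups

    groups = merge(motifs, [])

    # ---- fallback implied sub-motifs: only where the family offers no direct
    # evidence of the 0D core / 1D stack a higher-dimensional motif contains
    implied: list[_Motif] = []
    for m in motifs:
        want_0d = m.dim >= 1 and not any(
            g["dim"] == 0 and _sig_embed(g["signature"], m.signature, tol)
            for g in groups)
        want_1d = m.dim >= 2 and not any(
            g["dim"] == 1 and _sig_embed(g["signature"], m.signature, tol)
            for g in groups)
        implied.extend(_implied_submotifs(m, want_0d, want_1d, tol))
    implied.sort(key=lambda m: m.order)
    groups = merge(implied, groups)

    order_index = {sid: k for k, sid in enumerate(ids)}
    for g in groups:
        g["members"] = sorted(g["members"], key=lambda s: order_index[s])

    # ---- containment (full) between groups
    n = len(groups)
    contained = [[False] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            gx, gy = groups[x], groups[y]
            if gx["dim"] >= gy["dim"] or x == y:
                continue
            if not set(gy["members"]) <= set(gx["members"]):
                continue
            if _sig_embed(gx["signature"], gy["signature"], tol):
                contained[x][y] = True  # gx is a sub-construct of gy

    # ---- lineages (weakly connected components of containment) -> family letters
    import networkx as nx

    und = nx.Graph()
    und.add_nodes_from(range(n))
    for x in range(n):
        for y in range(n):
            if contained[x][y]:
                und.add_edge(x, y)
    comps = list(nx.connected_components(und))

    def comp_key(comp):
        dims = sorted(groups[i]["dim"] for i in comp)
        max_members = max(len(groups[i]["members"]) for i in comp)
        mags = sorted(min((min(m) for m in groups[i]["mags"]), default=0.0)
                      for i in comp)
        return (dims[0], -max_members, mags, min(sorted(groups[i]["members"])[0]
                                                 for i in comp))

    comps.sort(key=comp_key)
    letter_of = {}
    for ci, comp in enumerate(comps):
        letter = chr(ord("A") + ci)
        for gi in comp:
            letter_of[gi] = letter

    def group_key(gi):
        g = groups[gi]
        mag = min((min(m) for m in g["mags"]), default=0.0)
        return (letter_of[gi], g["dim"], round(mag, 3), g["members"])

    ordered = sorted(range(n), key=group_key)
    sc_ids = {}
    counters: dict[tuple, int] = {}
    for gi in ordered:
        key = (letter_of[gi], groups[gi]["dim"])
        counters[key] = counters.get(key, 0) + 1
        sc_ids[gi] = f"{letter_of[gi]}{groups[gi]['dim']}{counters[key]}"

    # ---- base-vector labels (t1, t2, ... in order of first appearance)
    registry: list[tuple[np.ndarray, float, str]] = []
    base_labels: dict[int, list[str]] = {}
    for gi in ordered:
        g = groups[gi]
        labels = []
        for k, v in enumerate(g["base_local"]):
            mag = float(np.mean(g["mags"][k]))
            vn = v / max(np.linalg.norm(v), 1e-12)
            found = None
            for rv, rmag, rlab in registry:
                ang = math.degrees(math.acos(np.clip(abs(float(vn @ rv)), 0.0, 1.0)))
                if abs(mag - rmag) <= tol.d and ang <= tol.ang:
                    found = rlab
                    break
            if found is None:
                found = f"t{len(registry) + 1}"
                registry.append((vn, mag, found))
            labels.append(found)
        base_labels[gi] = labels

    # ---- covering relations for the dependency column
    def covering(x):
        subs = [y for y in range(n) if contained[y][x]]
        cov = []
        for y in subs:
            if not any(contained[y][z] and z in subs and z != y for z in range(n)):
                cov.append(y)
        return cov

    def describe(gi):
        g = groups[gi]
        if g["dim"] == 0:
            parity = ("inversion-related pair"
                      if not g["signature"][0].desc.proper else "discrete pair")
            return f"0D {parity}"
        if g["dim"] == 1:
            return "1D stack/tape"
        if g["dim"] == 2:
            return "2D layer"
        return "3D isostructural set"

    constructs = []
    for gi in ordered:
        g = groups[gi]
        mags = [(round(min(m), 6), round(max(m), 6)) for m in g["mags"]]
        constructs.append(SupramolecularConstruct(
            sc_id=sc_ids[gi],
            dimensionality=g["dim"],
            members=list(g["members"]),
            base_vector_labels=base_labels[gi],
            base_magnitude_ranges=mags,
            sub_constructs=sorted(sc_ids[y] for y in range(n) if contained[y][gi]),
            dependencies=sorted(sc_ids[y] for y in covering(gi)),
            description=describe(gi),
            signature=g["signature"],
            base_local=g["base_local"],
        ))
    return FamilyResult(ids, constructs, tol, pairwise)
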