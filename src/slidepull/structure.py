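"""Geometry analyses on atomic coordinates.

Covers the structural side of the receptor-polysaccharide comparison:
optimal rigid-body (Kabsch) superposition and C-alpha RMSD between
structures, hydrogen-bond detection with geometric criteria (3.6 A
donor-acceptor cutoff; 120-180 deg acceptor...H-donor angle when
hydrogens are present), per-pair H-bond occupancies over a trajectory,
bridging-water classification and occupancy (binary/ternary/quaternary
interactions summed with a per-order cutoff), and per-residue RMSF
with apo/complex rigidification ratios.

Coordinates are carried as plain numpy arrays inside
:class:`StructureModel`; PDB files (multi-model PDB for trajectories)
are read and written through gemmi at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "Trajectory",
    "HBondCriteria",
    "HBond",
    "BridgeRecord",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "superpose_rmsd",
    "pair_calpha",
    "assign_donors_acceptors",
    "detect_hbonds",
    "hbond_occupancy",
    "bridging_water_occupancy",
    "rmsf",
    "rmsf_ratio",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4"}

#: Side-chain / terminal donor atoms of the standard amino acids.
_PROTEIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("LYS", "NZ"), ("TRP", "NE1"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
#: Covalent bond length cutoff for attaching hydrogens to heavy atoms, A.
_H_BOND_COVALENT_A = 1.25


@dataclass
class StructureModel:
    """A set of atoms with identity and coordinates (A).

    All identity fields are numpy arrays of equal length; boolean
    classification masks (donor/acceptor/water) are assigned lazily by
    :func:`assign_donors_acceptors`.
    """

    element: np.ndarray    # str, e.g. 'C', 'N', 'O', 'H'
    name: np.ndarray       # atom name, e.g. 'CA', 'OG1'
    resname: np.ndarray
    resseq: np.ndarray     # int
    chain: np.ndarray      # str
    coords: np.ndarray     # (n, 3) float, A

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.element)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for f in ("name", "resname", "resseq", "chain"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"{f} length mismatch")

    def __len__(self) -> int:
        return len(self.element)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.resname, list(WATER_RESNAMES))

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.element == "H"

    def has_hydrogens(self) -> bool:
        return bool(np.any(self.is_hydrogen))

    def select(self, *, chain: Optional[str] = None,
               resseq_range: Optional[Tuple[int, int]] = None,
               resnames: Optional[Sequence[str]] = None,
               heavy_only: bool = False,
               atom_names: Optional[Sequence[str]] = None) -> np.ndarray:
        """Boolean atom mask for a simple selection."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain == chain
        if resseq_range is not None:
            lo, hi = resseq_range
            mask &= (self.resseq >= lo) & (self.resseq <= hi)
        if resnames is not None:
            mask &= np.isin(self.resname, list(resnames))
        if heavy_only:
            mask &= ~self.is_hydrogen
        if atom_names is not None:
            mask &= np.isin(self.name, list(atom_names))
        return mask


@dataclass
class Trajectory:
    """An ordered list of frames sharing one topology."""

    topology: StructureModel
    frames: np.ndarray          # (n_frames, n_atoms, 3), A
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("every frame must match the topology atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> StructureModel:
        m = self.topology
        return StructureModel(m.element, m.name, m.resname, m.resseq, m.chain,
                              self.frames[i])


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    3.6 A cutoff for the acceptor...donor distance; 120-180 degree
    range for the acceptor...H-donor angle (only evaluated when
    hydrogen positions are available).
    """

    max_donor_acceptor_distance: float = 3.6
    angle_min: float = 120.0
    angle_max: float = 180.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 <= self.angle_min <= self.angle_max <= 180):
            raise ValueError("angle range must lie within [0, 180]")


@dataclass(frozen=True)
class HBond:
    donor_index: int
    acceptor_index: int
    hydrogen_index: Optional[int]
    distance: float
    angle: Optional[float]


@dataclass
class BridgeRecord:
    """A water bridging protein and ligand, with per-order occupancy.

    ``order_occupancy`` maps 'binary'/'ternary'/'quaternary' (2, 3, >=4
    simultaneous heavy-atom partners) to its frame fraction; ``occupancy``
    sums the orders that individually reach the minimum-component cutoff.
    """

    water_index: int            # index of the water oxygen atom
    water_resseq: int
    partner_atoms: List[int] = field(default_factory=list)
    order_occupancy: Dict[str, float] = field(default_factory=dict)
    occupancy: float = 0.0


# ---------------------------------------------------------------------------
# PDB I/O (gemmi at the boundary)


def _model_from_gemmi(gmodel) -> StructureModel:
    el, nm, rn, rs, ch, xyz = [], [], [], [], [], []
    for chain in gmodel:
        for res in chain:
            for atom in res:
                el.append(atom.element.name)
                nm.append(atom.name)
                rn.append(res.name)
                rs.append(res.seqid.num)
                ch.append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return StructureModel(np.array(el), np.array(nm), np.array(rn),
                          np.array(rs, dtype=int), np.array(ch),
                          np.array(xyz, dtype=float))


def read_structure(path) -> StructureModel:
    """Read the first model of a PDB (or mmCIF) file."""
    import gemmi
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    return _model_from_gemmi(st[0])


def read_trajectory(path, frame_interval_ps: float = 100.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (MODEL/ENDMDL blocks = frames)."""
    import gemmi
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    top = _model_from_gemmi(st[0])
    frames = []
    for gmodel in st:
        m = _model_from_gemmi(gmodel)
        if len(m) != len(top):
            raise ValueError(f"{path}: model atom counts differ")
        frames.append(m.coords)
    return Trajectory(top, np.stack(frames), frame_interval_ps)


def _to_gemmi(model: StructureModel, coords: Optional[np.ndarray] = None):
    import gemmi
    xyz = model.coords if coords is None else coords
    gmodel = gemmi.Model(1)
    chain_map: Dict[str, object] = {}
    res_map: Dict[Tuple[str, int, str], object] = {}
    for i in range(len(model)):
        cname = str(model.chain[i])
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
            gmodel.add_chain(chain_map[cname])
        chain = gmodel[cname]
        key = (cname, int(model.resseq[i]), str(model.resname[i]))
        if key not in res_map:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(int(model.resseq[i]), " ")
            chain.add_residue(res)
            res_map[key] = chain[-1]
        atom = gemmi.Atom()
        atom.name = str(model.name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        atom.pos = gemmi.Position(*xyz[i])
        res_map[key].add_atom(atom)
    return gmodel


def write_structure(model: StructureModel, path) -> Path:
    import gemmi
    st = gemmi.Structure()
    st.add_model(_to_gemmi(model))
    st.setup_entities()
    st.write_pdb(str(path))
    return Path(path)


def write_trajectory(traj: Trajectory, path) -> Path:
    import gemmi
    st = gemmi.Structure()
    for i in range(traj.n_frames):
        m = _to_gemmi(traj.topology, traj.frames[i])
        m.num = i + 1
        st.add_model(m)
    st.setup_entities()
    st.write_pdb(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# superposition


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray
                   ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of paired point sets (Kabsch/SVD).

    Returns (RMSD, rotation, translation) such that applying
    ``coords_b @ R.T + t`` brings b onto a with the globally minimal
    RMSD over all rotations and translations.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set: superposition not unique")
    H = b0.T @ a0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - (R @ cb)
    diff = (b0 @ R.T) - a0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return rmsd, R, t


def _chain_ca(model: StructureModel, chain: Optional[str]):
    mask = (model.name == "CA") & np.isin(model.resname, list(_STANDARD_AA))
    if chain is not None:
        mask &= model.chain == chain
    idx = np.nonzero(mask)[0]
    order = np.argsort(model.resseq[idx], kind="stable")
    return idx[order]

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def pair_calpha(model_a: StructureModel, model_b: StructureModel,
                alignment: str = "sequence",
                chain_a: Optional[str] = None, chain_b: Optional[str] = None
                ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Pair C-alpha atoms of two models for superposition.

    ``alignment='resnum'`` pairs residues sharing a residue number;
    ``alignment='sequence'`` pairs by global sequence alignment of the
    one-letter sequences (robust to deletions and renumbering). The
    pairing is deterministic and independent of atom order in the
    input. Returns paired coordinate arrays and the pair count.
    """
    ia = _chain_ca(model_a, chain_a)
    ib = _chain_ca(model_b, chain_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("no C-alpha atoms to pair")
    if alignment == "resnum":
        ra = {int(model_a.resseq[i]): i for i in ia}
        rb = {int(model_b.resseq[i]): i for i in ib}
        common = sorted(set(ra) & set(rb))
        if not common:
            raise ValueError("zero residue-number pairs")
        pa = np.array([ra[r] for r in common])
        pb = np.array([rb[r] for r in common])
    elif alignment == "sequence":
        from Bio import Align
        seq_a = "".join(_AA3TO1.get(str(model_a.resname[i]), "X") for i in ia)
        seq_b = "".join(_AA3TO1.get(str(model_b.resname[i]), "X") for i in ib)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aln = aligner.align(seq_a, seq_b)[0]
        pa_l, pb_l = [], []
        for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
            for off in range(a_end - a_start):
                pa_l.append(ia[a_start + off])
                pb_l.append(ib[b_start + off])
        if not pa_l:
            raise ValueError("zero aligned pairs")
        pa, pb = np.array(pa_l), np.array(pb_l)
    else:
        raise ValueError("alignment must be 'sequence' or 'resnum'")
    return model_a.coords[pa], model_b.coords[pb], len(pa)


# ---------------------------------------------------------------------------
# hydrogen bonds


def assign_donors_acceptors(model: StructureModel) -> Tuple[np.ndarray, np.ndarray]:
    """Default donor/acceptor heavy-atom masks.

    Acceptors: every N/O (and water O). Donors: backbone amide N and the
    classical side-chain donors of the standard amino acids; water O;
    and, for non-standard residues (e.g. the GlcNAc/GlcUA sugars of
    hyaluronan), every O/N — hydroxyls, amide N and glycosidic oxygens
    are all potential donors on a sugar. When hydrogens are present,
    donor status is additionally restricted at detection time to heavy
    atoms actually carrying a hydrogen.
    """
    n = len(model)
    is_no = np.isin(model.element, ["N", "O"])
    acceptor = is_no.copy()
    donor = np.zeros(n, dtype=bool)
    std = np.isin(model.resname, list(_STANDARD_AA))
    donor |= std & (model.name == "N")  # backbone amide
    for rn, an in _PROTEIN_DONORS:
        donor |= (model.resname == rn) & (model.name == an)
    donor |= model.is_water & (model.element == "O")
    donor |= (~std) & (~model.is_water) & is_no
    acceptor |= model.is_water & (model.element == "O")
    return donor, acceptor


def _attached_hydrogens(model: StructureModel, coords: np.ndarray) -> Dict[int, List[int]]:
    """Map heavy-atom index -> indices of covalently attached hydrogens."""
    h_idx = np.nonzero(model.is_hydrogen)[0]
    heavy_idx = np.nonzero(~model.is_hydrogen)[0]
    out: Dict[int, List[int]] = {}
    if len(h_idx) == 0:
        return out
    from scipy.spatial import cKDTree
    tree = cKDTree(coords[heavy_idx])
    dist, nearest = tree.query(coords[h_idx])
    for h, d, j in zip(h_idx, dist, nearest):
        if d <= _H_BOND_COVALENT_A:
            out.setdefault(int(heavy_idx[j]), []).append(int(h))
    return out


def detect_hbonds(model: StructureModel,
                  criteria: HBondCriteria = HBondCriteria(),
                  donor_mask: Optional[np.ndarray] = None,
                  acceptor_mask: Optional[np.ndarray] = None,
                  coords: Optional[np.ndarray] = None,
                  require_hydrogens: Optional[bool] = None) -> List[HBond]:
    """Detect hydrogen bonds in one frame.

    With hydrogens present (MD mode) a bond requires both the
    donor-acceptor distance cutoff and the acceptor...H-donor angle in
    the criteria range; without hydrogens (crystal mode) the distance
    criterion alone is applied. ``require_hydrogens=True`` raises if
    the model has no hydrogens instead of silently falling back.
    """
    xyz = model.coords if coords is None else np.asarray(coords, float)
    if donor_mask is None or acceptor_mask is None:
        d_auto, a_auto = assign_donors_acceptors(model)
        donor_mask = d_auto if donor_mask is None else donor_mask
        acceptor_mask = a_auto if acceptor_mask is None else acceptor_mask
    has_h = model.has_hydrogens()
    if require_hydrogens and not has_h:
        raise ValueError(
            "no hydrogen positions: the angle criterion cannot be evaluated; "
            "use crystal mode (require_hydrogens=False) for distance-only detection"
        )
    attached = _attached_hydrogens(model, xyz) if has_h else {}

    from scipy.spatial import cKDTree
    don = np.nonzero(donor_mask & ~model.is_hydrogen)[0]
    acc = np.nonzero(acceptor_mask & ~model.is_hydrogen)[0]
    if len(don) == 0 or len(acc) == 0:
        return []
    tree = cKDTree(xyz[acc])
    bonds: List[HBond] = []
    for di in don:
        if has_h and di not in attached:
            continue  # donor must carry a hydrogen in MD mode
        for jj in tree.query_ball_point(xyz[di], criteria.max_donor_acceptor_distance):
            ai = int(acc[jj])
            if ai == di:
                continue
            # skip partners within the same residue
            if (model.chain[ai] == model.chain[di]
                    and model.resseq[ai] == model.resseq[di]):
                continue
            dist = float(np.linalg.norm(xyz[ai] - xyz[di]))
            if dist > criteria.max_donor_acceptor_distance:
                continue
            if not has_h:
                bonds.append(HBond(int(di), ai, None, dist, None))
                continue
            best = None
            for hi in attached[di]:
                v1 = xyz[di] - xyz[hi]
                v2 = xyz[ai] - xyz[hi]
                cosang = float(np.dot(v1, v2) /
                               (np.linalg.norm(v1) * np.linalg.norm(v2)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if criteria.angle_min <= ang <= criteria.angle_max:
                    if best is None or ang > best[1]:
                        best = (hi, ang)
            if best is not None:
                bonds.append(HBond(int(di), ai, int(best[0]), dist, float(best[1])))
    return bonds


def hbond_occupancy(traj: Trajectory,
                    criteria: HBondCriteria = HBondCriteria(),
                    donor_mask: Optional[np.ndarray] = None,
                    acceptor_mask: Optional[np.ndarray] = None
                    ) -> Dict[Tuple[int, int], float]:
    """Per donor-acceptor pair occupancy over a trajectory.

    Occupancy is the exact fraction frames-with-bond / total frames.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    counts: Dict[Tuple[int, int], int] = {}
    for i in range(traj.n_frames):
        for b in detect_hbonds(traj.topology, criteria, donor_mask, acceptor_mask,
                               coords=traj.frames[i]):
            counts[(b.donor_index, b.acceptor_index)] = \
                counts.get((b.donor_index, b.acceptor_index), 0) + 1
    return {k: v / traj.n_frames for k, v in counts.items()}


_ORDER_NAMES = {2: "binary", 3: "ternary", 4: "quaternary"}


def bridging_water_occupancy(traj: Trajectory,
                             protein_mask: np.ndarray,
                             ligand_mask: np.ndarray,
                             criteria: HBondCriteria = HBondCriteria(),
                             min_component: float = 0.10) -> List[BridgeRecord]:
    """Occupancy of waters bridging protein and ligand.

    In each frame a water bridges when it is simultaneously H-bonded to
    at least one protein atom and one ligand atom; the interaction
    order is the number of simultaneous heavy-atom partners (2 =
    binary, 3 = ternary, >= 4 = quaternary). Per water, the total
    occupancy sums the orders whose individual occupancy reaches
    ``min_component``.
    """
    top = traj.topology
    water_o = np.nonzero(top.is_water & (top.element == "O"))[0]
    if len(water_o) == 0:
        return []
    per_water_order_counts: Dict[int, Dict[str, int]] = {int(w): {} for w in water_o}
    per_water_partners: Dict[int, set] = {int(w): set() for w in water_o}
    donor_mask, acceptor_mask = assign_donors_acceptors(top)
    for i in range(traj.n_frames):
        bonds = detect_hbonds(top, criteria, donor_mask, acceptor_mask,
                              coords=traj.frames[i])
        frame_partners: Dict[int, set] = {}
        for b in bonds:
            for w, other in ((b.donor_index, b.acceptor_index),
                             (b.acceptor_index, b.donor_index)):
                if w in per_water_order_counts and not top.is_water[other]:
                    frame_partners.setdefault(w, set()).add(other)
        for w, partners in frame_partners.items():
            has_prot = any(protein_mask[p] for p in partners)
            has_lig = any(ligand_mask[p] for p in partners)
            if not (has_prot and has_lig):
                continue
            order = _ORDER_NAMES.get(min(len(partners), 4))
            per_water_order_counts[w][order] = per_water_order_counts[w].get(order, 0) + 1
            per_water_partners[w] |= partners
    records: List[BridgeRecord] = []
    for w in water_o:
        w = int(w)
        if not per_water_order_counts[w]:
            continue
        order_occ = {k: v / traj.n_frames for k, v in per_water_order_counts[w].items()}
        total = sum(v for v in order_occ.values() if v >= min_component)
        records.append(BridgeRecord(
            water_index=w,
            water_resseq=int(top.resseq[w]),
            partner_atoms=sorted(per_water_partners[w]),
            order_occupancy=order_occ,
            occupancy=total,
        ))
    return records


# ---------------------------------------------------------------------------
# RMSF


def rmsf(traj: Trajectory, align_mask: np.ndarray,
         report_mask: Optional[np.ndarray] = None,
         n_iterations: int = 3) -> pd.Series:
    """Per-residue RMSF (A) after iterative superposition onto the mean.

    Frames are rigid-body aligned on ``align_mask`` atoms onto the
    running mean structure (iterated to convergence of the reference);
    the per-residue RMSF is the rms of per-atom fluctuations over the
    heavy atoms of each residue in ``report_mask``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not np.any(align_mask):
        raise ValueError("empty alignment selection")
    top = traj.topology
    if report_mask is None:
        report_mask = ~top.is_hydrogen
    if not np.any(report_mask):
        raise ValueError("empty report selection")
    frames = traj.frames.copy()
    ref = frames[0, align_mask]
    for _ in range(n_iterations):
        for i in range(traj.n_frames):
            _, R, t = superpose_rmsd(ref, frames[i, align_mask])
            frames[i] = frames[i] @ R.T + t
        ref = frames[:, align_mask].mean(axis=0)
    mean = frames.mean(axis=0)
    msf = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)  # per atom

    keys, values = [], []
    idx = np.nonzero(report_mask)[0]
    frame_df = pd.DataFrame({
        "chain": top.chain[idx], "resseq": top.resseq[idx], "msf": msf[idx],
    })
    for (ch, rs), grp in frame_df.groupby(["chain", "resseq"], sort=True):
        keys.append((ch, int(rs)))
        values.append(float(np.sqrt(grp["msf"].mean())))
    return pd.Series(values, index=pd.MultiIndex.from_tuples(keys, names=["chain", "resseq"]),
                     name="rmsf_A")


def rmsf_ratio(apo: pd.Series, complexed: pd.Series,
               residues: Optional[Sequence] = None) -> Tuple[pd.Series, float]:
    """Elementwise RMSF_apo / RMSF_complex and its mean over ``residues``.

    Residues with zero complex RMSF yield NaN (undefined) and are
    excluded from the mean.
    """
    common = apo.index.intersection(complexed.index)
    if residues is not None:
        sel = [r for r in residues if r in common]
        if not sel:
            raise ValueError("requested residues absent from both inputs")
        common = pd.MultiIndex.from_tuples(sel, names=apo.index.names) \
            if isinstance(common, pd.MultiIndex) else pd.Index(sel)
    a = apo.loc[common]
    c = complexed.loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = a / c.replace(0.0, np.nan)
    return ratios, float(ratios.dropna().mean())
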