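"""Conserved-water labeling from pairs of superposed homologous structures.

The procedure mirrors the standard homolog-comparison definition of water
conservation:

1. superpose the homolog onto the reference with an optimal least-squares
   rigid fit over matched Cα atoms (Kabsch);
2. discard pairs whose superposition RMSD exceeds 2.0 Å — poorly matching
   homologs make water comparison meaningless;
3. define the binding pocket as every protein atom and water oxygen within
   7.0 Å of any ligand atom (inclusive);
4. for each pocket water of the reference, compute the nearest Euclidean
   distance (NED) to any water oxygen of the transformed homolog, and call
   the water conserved (CWM) when NED <= 1.2 Å, free (FWM) otherwise.

All distances are oxygen-oxygen (waters are represented by their oxygen).
Both the 7.0 Å and 1.2 Å thresholds are inclusive.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel, WaterSite, water_sites

__all__ = [
    "LabelingConfig",
    "SuperpositionResult",
    "PairRejectedError",
    "superpose",
    "pair_passes_filter",
    "define_pocket",
    "nearest_water_distance",
    "label_waters",
    "match_calpha_pairs",
]


class PairRejectedError(ValueError):
    """The homolog pair failed the superposition RMSD filter."""


class DegenerateGeometryError(ValueError):
    """Matched point sets are too few or collinear for a unique rigid fit."""


@dataclass(frozen=True)
class LabelingConfig:
    """Thresholds of the labeling procedure (all Å, all inclusive).

    ``pocket_mode`` selects how the pocket is delimited: ``"any_atom"``
    (distance to the closest ligand atom, the default) or ``"centroid"``
    (distance to the ligand geometric centre).
    """

    rmsd_max: float = 2.0
    pocket_radius: float = 7.0
    ned_threshold: float = 1.2
    pocket_mode: str = "any_atom"

    def __post_init__(self) -> None:
        if min(self.rmsd_max, self.pocket_radius, self.ned_threshold) <= 0:
            raise ValueError("all labeling thresholds must be strictly positive")
        if self.pocket_mode not in ("any_atom", "centroid"):
            raise ValueError(f"unknown pocket_mode {self.pocket_mode!r}")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile coordinates onto the reference."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å over the matched atom set
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map (n, 3) mobile-frame coordinates into the reference frame."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return coords @ self.rotation.T + self.translation


def _kabsch(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation such that R @ mob + t ≈ ref."""
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = ref - ref_c
    q = mob - mob_c
    # degeneracy: need at least two independent directions in each cloud
    for cloud, name in ((p, "reference"), (q, "mobile")):
        s = np.linalg.svd(cloud, compute_uv=False)
        if s[0] <= 0 or s[1] / s[0] < 1e-8:
            raise DegenerateGeometryError(f"{name} matched atoms are collinear or coincident")
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    return rot, trans


def superpose(
    reference: StructureModel,
    mobile: StructureModel,
    atom_matching: list[tuple[tuple[str, int, str], tuple[str, int, str]]] | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of *mobile* onto *reference*.

    *atom_matching* pairs atoms by ``(chain_id, residue_number, atom_name)``
    keys, reference first.  When omitted, Cα atoms of residues paired by a
    global sequence alignment of the chains are used
    (:func:`match_calpha_pairs`).
    """
    if atom_matching is None:
        atom_matching = match_calpha_pairs(reference, mobile)
    if len(atom_matching) < 3:
        raise DegenerateGeometryError(
            f"need at least 3 matched atom pairs, got {len(atom_matching)}"
        )
    ref_index = {(a.chain_id, a.residue_number, a.name): a for a in reference.atoms}
    mob_index = {(a.chain_id, a.residue_number, a.name): a for a in mobile.atoms}
    try:
        ref_xyz = np.array([ref_index[r].position for r, _ in atom_matching], dtype=float)
        mob_xyz = np.array([mob_index[m].position for _, m in atom_matching], dtype=float)
    except KeyError as exc:
        raise ValueError(f"matched atom {exc.args[0]} absent from structure") from None
    rot, trans = _kabsch(ref_xyz, mob_xyz)
    moved = mob_xyz @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_matched=len(atom_matching))


def match_calpha_pairs(
    reference: StructureModel, mobile: StructureModel
) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Pair Cα atoms via global sequence alignment of the protein chains.

    Chains are paired greedily by alignment score; aligned, non-gap residue
    pairs contribute their Cα atoms.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.SeqUtils import seq1

    def chain_calphas(model: StructureModel):
        chains: dict[str, list] = {}
        for a in model.protein_atoms:
            if a.name == "CA":
                chains.setdefault(a.chain_id, []).append(a)
        out = {}
        for cid, atoms in chains.items():
            atoms.sort(key=lambda a: a.residue_number)
            seq = "".join(seq1(a.residue_name, undef_code="X") or "X" for a in atoms)
            out[cid] = (seq, atoms)
        return out

    ref_chains = chain_calphas(reference)
    mob_chains = chain_calphas(mobile)
    if not ref_chains or not mob_chains:
        raise ValueError("superposition requires Cα atoms in both structures")

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"

    scored = []
    for rc, (rseq, _) in ref_chains.items():
        for mc, (mseq, _) in mob_chains.items():
            scored.append((aligner.score(rseq, mseq), rc, mc))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))

    pairs = []
    used_ref: set[str] = set()
    used_mob: set[str] = set()
    for _, rc, mc in scored:
        if rc in used_ref or mc in used_mob:
            continue
        used_ref.add(rc)
        used_mob.add(mc)
        rseq, ratoms = ref_chains[rc]
        mseq, matoms = mob_chains[mc]
        aln = aligner.align(rseq, mseq)[0]
        for (rs, re_), (ms, me) in zip(*aln.aligned):
            for i, j in zip(range(rs, re_), range(ms, me)):
                ra, ma = ratoms[i], matoms[j]
                pairs.append(
                    ((ra.chain_id, ra.residue_number, ra.name), (ma.chain_id, ma.residue_number, ma.name))
                )
    return pairs


def pair_passes_filter(result: SuperpositionResult, config: LabelingConfig | None = None) -> bool:
    """True iff the superposition RMSD is within the retention threshold (inclusive)."""
    config = config or LabelingConfig()
    return result.rmsd <= config.rmsd_max


def define_pocket(
    model: StructureModel, config: LabelingConfig | None = None
) -> tuple[list, list[WaterSite]]:
    """Binding-pocket protein atoms and waters of *model*.

    Membership: minimum Euclidean distance to any ligand atom
    <= ``pocket_radius`` (or distance to the ligand centroid in
    ``"centroid"`` mode).  Returned waters carry ``in_pocket=True``.
    """
    config = config or LabelingConfig()
    ligand_xyz = model.coords("ligand")
    if ligand_xyz.shape[0] == 0:
        raise ValueError(f"{model.structure_id}: no ligand atoms; cannot define the pocket")
    if config.pocket_mode == "centroid":
        ligand_xyz = ligand_xyz.mean(axis=0, keepdims=True)
    tree = cKDTree(ligand_xyz)

    def min_dist(points: np.ndarray) -> np.ndarray:
        if points.shape[0] == 0:
            return np.empty(0)
        d, _ = tree.query(points, k=1)
        return np.atleast_1d(d)

    protein = model.protein_atoms
    dprot = min_dist(model.coords("protein"))
    pocket_protein = [a for a, d in zip(protein, dprot) if d <= config.pocket_radius]

    sites = water_sites(model)
    dwat = min_dist(np.array([s.position for s in sites]) if sites else np.empty((0, 3)))
    pocket_waters = []
    for s, d in zip(sites, dwat):
        if d <= config.pocket_radius:
            s.in_pocket = True
            pocket_waters.append(s)
    return pocket_protein, pocket_waters


def conservation_label(ned: float, config: LabelingConfig | None = None) -> str:
    """CWM iff the nearest-water distance is within the threshold (inclusive)."""
    config = config or LabelingConfig()
    return "CWM" if ned <= config.ned_threshold else "FWM"


def nearest_water_distance(site: WaterSite, partner_positions: np.ndarray) -> float:
    """Minimum oxygen-oxygen distance from *site* to the partner waters.

    Partner coordinates must already be in the reference frame.  Returns
    ``math.inf`` when there are no partners (downstream label FWM).
    """
    partner_positions = np.asarray(partner_positions, dtype=float).reshape(-1, 3)
    if partner_positions.shape[0] == 0:
        return float("inf")
    return float(np.min(np.linalg.norm(partner_positions - site.position, axis=1)))


def label_waters(
    reference: StructureModel,
    homolog: StructureModel,
    config: LabelingConfig | None = None,
    atom_matching=None,
) -> list[WaterSite]:
    """Run the full labeling pipeline on one homolog pair.

    Returns every water site of the reference: pocket waters carry a
    CWM/FWM label and their NED; waters outside the pocket stay unlabeled.
    Candidate partners are *all* waters of the homolog (no pocket
    restriction on the homolog side).

    Raises :class:`PairRejectedError` when the superposition RMSD exceeds
    the filter threshold — a rejected pair is an explicit failure, never a
    silently empty result.
    """
    config = config or LabelingConfig()
    sup = superpose(reference, homolog, atom_matching)
    if not pair_passes_filter(sup, config):
        raise PairRejectedError(
            f"pair rejected (RMSD): {sup.rmsd:.3f} Å > {config.rmsd_max:.3f} Å "
            f"over {sup.n_matched} matched atoms"
        )

    hom_waters = sup.apply(homolog.coords("water")) if homolog.water_atoms else np.empty((0, 3))

    all_sites = water_sites(reference)
    _, pocket = define_pocket(reference, config)
    pocket_keys = {(s.chain_id, s.residue_number) for s in pocket}
    for site in all_sites:
        if (site.chain_id, site.residue_number) not in pocket_keys:
            continue
        site.in_pocket = True
        site.ned = nearest_water_distance(site, hom_waters)
        site.label = conservation_label(site.ned, config)
    return all_sites


def labeled_sites_frame(sites: list[WaterSite]):
    """Tabular view of labeled sites (columns of the label report TSV)."""
    import pandas as pd

    rows = [
        {
            "structure_id": s.source_id,
            "chain": s.chain_id,
            "resnum": s.residue_number,
            "x": s.position[0],
            "y": s.position[1],
            "z": s.position[2],
            "ned": s.ned if s.ned is not None and np.isfinite(s.ned) else np.nan,
            "label": s.label,
        }
        for s in sites
    ]
    return pd.DataFrame(rows)
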