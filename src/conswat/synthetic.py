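"""Synthetic fixtures with planted ground truth.

Two generators make every pipeline stage testable without touching any
structure repository:

* :func:`generate_homolog_pair` builds a toy protein-ligand structure (a
  spherical residue cage around a small ligand, binding-site waters inside
  and bulk waters outside) plus a homolog copy in which a chosen fraction
  of the pocket waters is kept in place (sub-threshold jitter) and the rest
  displaced well beyond the conservation threshold, the whole homolog then
  moved by a random rigid transform.  The planted conserved/free labels are
  unambiguous by construction and are verified against the construction
  geometry before the pair is returned.

* :func:`generate_feature_table` draws labeled six-feature rows from
  truncated normal distributions parameterised per class by (min, max,
  mean) summary statistics, with the location solved so the *truncated*
  mean hits the requested target.  Defaults emulate the class-wise
  marginals typical of conserved vs free binding-site waters in
  high-resolution crystal structures (conserved: dense, hydrophilic,
  buried, low B-factor and mobility) at the ~1 : 1.25 FWM : CWM class
  ratio of curated homolog-pair corpora.

All randomness flows from a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .structure_io import AtomRecord, StructureModel

__all__ = [
    "StructureSimSpec",
    "FeatureSimSpec",
    "CLASS_FEATURE_STATS",
    "generate_homolog_pair",
    "generate_feature_table",
]

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# local atom geometry of one coarse residue (N, CA, C, O, CB around the centre)
_RESIDUE_OFFSETS = {
    "N": (-1.2, 0.3, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.4, 0.0),
    "O": (1.6, 1.4, 0.4),
    "CB": (-0.2, -1.1, 0.9),
}
_RESIDUE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class StructureSimSpec:
    """Geometry and noise settings of a planted homolog pair.

    ``displacement_min`` must exceed the 1.2 Å conservation threshold and
    ``jitter_sd`` must stay small enough (< 0.4 Å) that no planted label is
    ambiguous after superposition.
    """

    n_protein_atoms: int = 300
    n_pocket_waters: int = 40
    n_far_waters: int = 10
    conserved_fraction: float = 0.556
    displacement_min: float = 2.0
    jitter_sd: float = 0.12
    protein_jitter_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must lie in [0, 1]")
        if self.displacement_min <= 1.2:
            raise ValueError("displacement_min must exceed the 1.2 Å conservation threshold")
        if not 0.0 <= self.jitter_sd < 0.4:
            raise ValueError("jitter_sd must be below 0.4 Å to keep planted labels unambiguous")


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / ((1.0 + np.sqrt(5.0)) / 2.0)
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_separated(
    rng: np.random.Generator,
    n: int,
    radial: tuple[float, float],
    existing: list[np.ndarray],
    min_sep: float,
) -> list[np.ndarray]:
    """Rejection-sample n points in a radial shell, pairwise >= min_sep apart."""
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        tries += 1
        if tries > 200000:
            raise RuntimeError("could not place waters with the requested separation; reduce counts")
        p = _random_unit(rng) * rng.uniform(*radial)
        if all(np.linalg.norm(p - q) >= min_sep for q in existing + points):
            points.append(p)
    return points


def generate_homolog_pair(
    spec: StructureSimSpec | None = None,
) -> tuple[StructureModel, StructureModel, dict[tuple[str, int], str]]:
    """Reference structure, rigidly transformed homolog, and planted labels.

    Truth maps ``(chain_id, residue_number)`` of each pocket water of the
    reference to ``"CWM"`` or ``"FWM"``; far (non-pocket) waters are absent
    from the map.  The construction is re-checked: every conserved water's
    nearest homolog water (in the common frame) lies within 0.8 Å, every
    displaced water's beyond 1.6 Å, so the 1.2 Å rule recovers the truth
    exactly once the homolog is superposed back.
    """
    spec = spec or StructureSimSpec()
    rng = np.random.default_rng(spec.seed)

    # ligand: a small heavy-atom cluster at the origin
    ligand_xyz = np.array(
        [[0, 0, 0], [1.1, 0.3, 0], [-0.9, 0.7, 0.4], [0.2, -1.0, 0.6], [0.5, 0.8, -0.9], [-0.4, -0.5, -0.8]],
        dtype=float,
    )

    # protein cage: coarse residues on a sphere so waters near the ligand are buried
    n_res = max(3, spec.n_protein_atoms // len(_RESIDUE_OFFSETS))
    centres = _fibonacci_directions(n_res) * 8.5
    sequence = [ _AA20[int(k)] for k in rng.integers(0, len(_AA20), size=n_res) ]

    # waters: pocket shell inside the cage, far shell outside
    pocket_xyz = _sample_separated(rng, spec.n_pocket_waters, (2.5, 6.9), [], 2.7)
    far_xyz = _sample_separated(rng, spec.n_far_waters, (12.5, 16.0), pocket_xyz, 2.7)

    n_conserved = int(round(spec.conserved_fraction * spec.n_pocket_waters))
    conserved_idx = set(rng.choice(spec.n_pocket_waters, size=n_conserved, replace=False).tolist())

    # homolog waters in the common (reference) frame, re-checked for ambiguity
    hom_water_xyz = [None] * spec.n_pocket_waters
    for i, p in enumerate(pocket_xyz):
        for _ in range(200):
            if i in conserved_idx:
                cand = p + rng.normal(scale=spec.jitter_sd, size=3)
                ok = np.linalg.norm(cand - p) <= 0.8
            else:
                cand = p + _random_unit(rng) * rng.uniform(spec.displacement_min, spec.displacement_min + 0.8)
                ok = True
            if ok and all(
                np.linalg.norm(cand - q) >= 1.6 for j, q in enumerate(pocket_xyz) if j != i
            ):
                hom_water_xyz[i] = cand
                break
        else:
            raise RuntimeError("failed to place an unambiguous homolog water")
    hom_far_xyz = [p + rng.normal(scale=spec.jitter_sd, size=3) for p in far_xyz]

    # verify planted truth against the construction geometry
    all_hom = np.array(hom_water_xyz + hom_far_xyz)
    for i, p in enumerate(pocket_xyz):
        ned = float(np.min(np.linalg.norm(all_hom - p, axis=1)))
        want_conserved = i in conserved_idx
        if want_conserved and ned > 0.8:
            raise RuntimeError("planted conserved water drifted beyond the safety margin")
        if not want_conserved and ned < 1.6:
            raise RuntimeError("planted displaced water landed too close to a homolog water")

    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-20.0, 20.0, size=3)

    def build(structure_id: str, water_xyz: list[np.ndarray], far: list[np.ndarray], transform: bool, water_b: list[float], jitter_protein: bool) -> StructureModel:
        atoms: list[AtomRecord] = []
        serial = 1

        def place(xyz: np.ndarray) -> tuple[float, float, float]:
            if transform:
                xyz = rotation @ xyz + translation
            return tuple(np.round(xyz, 3))

        for ri, (centre, resname) in enumerate(zip(centres, sequence), start=1):
            for atom_name, offset in _RESIDUE_OFFSETS.items():
                xyz = centre + np.asarray(offset)
                if jitter_protein:
                    xyz = xyz + rng.normal(scale=spec.protein_jitter_sd, size=3)
                atoms.append(
                    AtomRecord(serial, atom_name, _RESIDUE_ELEMENTS[atom_name], resname, "A", ri,
                               place(xyz), 1.0, 20.0, "protein")
                )
                serial += 1
        for li, xyz in enumerate(ligand_xyz, start=1):
            atoms.append(AtomRecord(serial, f"C{li}", "C", "LIG", "L", 1, place(xyz), 1.0, 25.0, "ligand"))
            serial += 1
        for wi, xyz in enumerate(list(water_xyz) + list(far), start=1):
            atoms.append(
                AtomRecord(serial, "O", "O", "HOH", "W", wi, place(xyz), 1.0, water_b[wi - 1], "water")
            )
            serial += 1
        return StructureModel(structure_id, atoms)

    n_waters = spec.n_pocket_waters + spec.n_far_waters
    ref_b = [
        float(np.clip(rng.normal(23.7, 5.0) if i in conserved_idx else rng.normal(36.4, 8.0), 2.0, 95.0))
        for i in range(n_waters)
    ]
    hom_b = [float(np.clip(rng.normal(30.0, 8.0), 2.0, 95.0)) for _ in range(n_waters)]

    reference = build(f"ref{spec.seed}", pocket_xyz, far_xyz, transform=False, water_b=ref_b, jitter_protein=False)
    homolog = build(f"hom{spec.seed}", hom_water_xyz, hom_far_xyz, transform=True, water_b=hom_b, jitter_protein=spec.protein_jitter_sd > 0)

    truth = {
        ("W", i + 1): ("CWM" if i in conserved_idx else "FWM")
        for i in range(spec.n_pocket_waters)
    }
    return reference, homolog, truth


# ---------------------------------------------------------------------------
# labeled feature tables


#: Per-class (min, max, mean) of the six features A–F: conserved waters are
#: denser, more hydrophilic/hydrophobic-contacted, more buried, stiffer.
CLASS_FEATURE_STATS: dict[str, dict[str, tuple[float, float, float]]] = {
    "CWM": {
        "A": (0.000, 12.000, 3.033),
        "B": (0.027, 12.289, 1.099),
        "C": (0.000, 94.670, 23.740),
        "D": (0.005, 0.243, 0.071),
        "E": (0.000, 0.505, 0.116),
        "F": (0.000, 40.877, 6.683),
    },
    "FWM": {
        "A": (0.000, 7.000, 1.146),
        "B": (0.000, 8.992, 1.673),
        "C": (0.000, 99.930, 36.371),
        "D": (0.000, 0.147, 0.029),
        "E": (0.000, 0.249, 0.049),
        "F": (0.000, 84.949, 21.877),
    },
}


@dataclass(frozen=True)
class FeatureSimSpec:
    """Sampling plan for a labeled feature table.

    ``class_ratio`` is CWM rows per FWM row (1.25 by default, i.e. a
    1 : 1.25 FWM : CWM imbalance).  ``separation`` scales the distance of
    the two class means from their midpoint, feature by feature; 1.0
    reproduces the default statistics, larger values make the classes more
    distinguishable.
    """

    n: int = 4500
    class_ratio: float = 1.25
    seed: int = 0
    separation: float = 1.0
    stats: dict = field(default_factory=lambda: CLASS_FEATURE_STATS)

    def __post_init__(self) -> None:
        if self.n < 2 or self.class_ratio <= 0 or self.separation < 0:
            raise ValueError("invalid feature-table spec")


def _truncnorm_sampler(lo: float, hi: float, target_mean: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample n truncated normals on [lo, hi] whose true mean equals target_mean.

    The scale is set so ~99% of the untruncated mass lies in bounds; the
    location is then solved by fixed-point iteration so the truncated
    distribution's mean matches the target (truncation alone would bias it).
    """
    if not lo <= target_mean <= hi:
        raise ValueError(f"infeasible truncation: mean {target_mean} outside [{lo}, {hi}]")
    scale = max(min(target_mean - lo, hi - target_mean) / 2.576, 1e-9)
    if scale <= 1e-9:  # mean sits on a bound: distribution collapses there
        return np.full(n, target_mean)
    loc = target_mean
    for _ in range(40):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m = truncnorm.mean(a, b, loc=loc, scale=scale)
        if abs(m - target_mean) < 1e-10:
            break
        loc += target_mean - m
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_feature_table(spec: FeatureSimSpec | None = None) -> pd.DataFrame:
    """Labeled feature table with class-wise truncated-normal marginals.

    Columns A–F plus ``label``; rows shuffled; per-class sample means land
    within sampling noise (≈3 standard errors) of the requested targets.
    """
    spec = spec or FeatureSimSpec()
    rng = np.random.default_rng(spec.seed)
    n_cwm = int(round(spec.n * spec.class_ratio / (1.0 + spec.class_ratio)))
    n_fwm = spec.n - n_cwm
    counts = {"CWM": n_cwm, "FWM": n_fwm}

    letters = sorted(next(iter(spec.stats.values())).keys())
    for label, feats in spec.stats.items():
        for letter, (lo, hi, mean) in feats.items():
            if not (lo <= mean <= hi) or lo >= hi:
                raise ValueError(
                    f"infeasible truncation bounds for {label}/{letter}: mean {mean} vs [{lo}, {hi}]"
                )
    midpoints = {
        letter: 0.5 * (spec.stats["CWM"][letter][2] + spec.stats["FWM"][letter][2])
        for letter in letters
    }

    frames = []
    for label in ("FWM", "CWM"):
        cols: dict[str, np.ndarray] = {}
        for letter in letters:
            lo, hi, mean = spec.stats[label][letter]
            target = midpoints[letter] + spec.separation * (mean - midpoints[letter])
            target = float(np.clip(target, lo, hi))
            cols[letter] = _truncnorm_sampler(lo, hi, target, rng, counts[label])
        df = pd.DataFrame(cols)
        df["label"] = label
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)
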