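"""Six microenvironment features of a binding-site water.

For each water oxygen the module computes, against the protein context of
its structure:

A. **atom density** — number of protein atoms within 3.6 Å;
B. **mobility** — B-factor normalised by the structure-mean water B-factor,
   divided by occupancy normalised by the structure-mean water occupancy;
C. **B-factor** — the crystallographic temperature factor, taken verbatim
   from the coordinate file (8π²·Ū² for mean displacement Ū);
D. **atomic hydrophilicity** — Σ h_i · exp(−r_i/d₀) over protein atoms
   within 4 Å, h_i the per-atom-type hydration propensity;
E. **atomic hydrophobicity** — the same sum with the carbon (lipophilic)
   propensity l_i in place of h_i;
F. **SASA** — solvent-accessible surface area of the water-oxygen sphere
   (vdW radius + 1.4 Å probe) against the protein atoms, by Shrake–Rupley
   sphere-point sampling.

Conserved waters sit in concave, densely packed, hydrophilic pockets: high
density and hydrophilicity, low SASA, low B-factor and mobility.  The
distance-weighted sums use a negative exponent, so each neighbour's
contribution decays with distance — the natural interaction weighting; a
config switch flips the sign for the (unbounded) positive-exponent variant.

Letter codes A–F are the canonical ordering used by the feature-combination
evaluator and all report tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import StructureModel, WaterSite, water_sites

logger = logging.getLogger("conswat.features")

#: Letter code -> feature name, in evaluator order.
FEATURE_LETTERS: dict[str, str] = {
    "A": "atom_density",
    "B": "mobility",
    "C": "bfactor",
    "D": "hydrophilicity",
    "E": "hydrophobicity",
    "F": "sasa",
}

#: Standard heavy-atom van der Waals radii (Å), NACCESS-style.
DEFAULT_VDW: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}


@dataclass(frozen=True)
class FeatureConfig:
    """Radii and numerical knobs of the feature calculations (Å).

    ``d0`` is the interaction distance scale of the propensity-weighted
    sums; it is not fixed by the formulation, so it must be explicit in any
    serialised configuration.  ``positive_exponent`` switches the
    propensity weights from exp(−r/d₀) to exp(+r/d₀).
    ``sasa_context`` selects which atoms occlude the water sphere:
    ``"protein"`` (default) or ``"all"`` (protein + ligand + other waters).
    ``mobility_scope`` sets the normalisation baseline of the mobility
    feature: ``"all"`` water oxygens of the structure (default) or
    ``"pocket"`` waters only (caller restricts the site list).
    """

    density_radius: float = 3.6
    propensity_radius: float = 4.0
    d0: float = 1.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    vdw_radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW))
    positive_exponent: bool = False
    sasa_context: str = "protein"
    mobility_scope: str = "all"

    def __post_init__(self) -> None:
        if min(self.density_radius, self.propensity_radius, self.d0, self.probe_radius) <= 0:
            raise ValueError("all feature radii and d0 must be strictly positive")
        if self.sasa_points < 92:
            raise ValueError("sasa_points must be at least 92")

    def vdw(self, element: str) -> float:
        try:
            return self.vdw_radii[element.upper()]
        except KeyError:
            raise KeyError(f"no van der Waals radius configured for element {element!r}") from None


@dataclass(frozen=True)
class FeatureVector:
    """The six per-water features, in A–F letter order."""

    atom_density: int
    mobility: float
    bfactor: float
    hydrophilicity: float
    hydrophobicity: float
    sasa: float

    def as_dict(self) -> dict[str, float]:
        return {letter: getattr(self, name) for letter, name in FEATURE_LETTERS.items()}


class PropensityTable:
    """Per-atom-type hydration (h) and carbon/lipophilic (l) propensities.

    Lookup order for a protein atom: exact ``(residue, atom-name)`` key,
    then wildcard-residue atom-name key, then element class, then a
    configurable default (0 with a logged warning).  The shipped default
    table encodes the usual pattern — polar oxygens and nitrogens hydrate
    strongly, carbons carry the lipophilic weight — and is fully
    user-replaceable via :meth:`from_tsv`.
    """

    def __init__(
        self,
        exact: dict[tuple[str, str], tuple[float, float]],
        by_atom: dict[str, tuple[float, float]],
        by_element: dict[str, tuple[float, float]],
        default: tuple[float, float] = (0.0, 0.0),
        provenance: str = "user",
    ) -> None:
        self.exact = exact
        self.by_atom = by_atom
        self.by_element = by_element
        self.default = default
        self.provenance = provenance
        self._warned: set[tuple[str, str]] = set()

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "PropensityTable":
        df = pd.read_csv(path, sep="\t", dtype={"residue": str, "atom": str})
        exact: dict = {}
        by_atom: dict = {}
        by_element: dict = {}
        for row in df.itertuples(index=False):
            hl = (float(row.h), float(row.l))
            if row.residue == "element":
                by_element[row.atom.upper()] = hl
            elif row.residue == "*":
                by_atom[row.atom.upper()] = hl
            else:
                exact[(row.residue.upper(), row.atom.upper())] = hl
        return cls(exact, by_atom, by_element, provenance=provenance or str(path))

    @classmethod
    def default_table(cls) -> "PropensityTable":
        with resources.as_file(resources.files("conswat.data") / "propensities.tsv") as p:
            table = cls.from_tsv(p, provenance="conswat-builtin")
        return table

    def lookup(self, residue_name: str, atom_name: str, element: str) -> tuple[float, float]:
        key = (residue_name.upper(), atom_name.upper())
        if key in self.exact:
            return self.exact[key]
        if key[1] in self.by_atom:
            return self.by_atom[key[1]]
        if element.upper() in self.by_element:
            return self.by_element[element.upper()]
        if key not in self._warned:
            self._warned.add(key)
            logger.warning(
                "no propensity for atom %s/%s (element %s); using default %s",
                residue_name, atom_name, element, self.default,
            )
        return self.default


# ---------------------------------------------------------------------------
# individual features


def atom_density(site: WaterSite, model: StructureModel, config: FeatureConfig | None = None) -> int:
    """Number of protein atoms within ``density_radius`` (inclusive) of the water oxygen."""
    config = config or FeatureConfig()
    coords = model.coords("protein")
    if coords.shape[0] == 0:
        return 0
    tree = cKDTree(coords)
    return int(len(tree.query_ball_point(site.position, r=config.density_radius)))


def _propensity_sum(
    site: WaterSite,
    model: StructureModel,
    table: PropensityTable,
    config: FeatureConfig,
    index: int,
) -> float:
    atoms = model.protein_atoms
    if not atoms:
        return 0.0
    coords = model.coords("protein")
    dists = np.linalg.norm(coords - site.position, axis=1)
    sign = 1.0 if config.positive_exponent else -1.0
    total = 0.0
    for atom, r in zip(atoms, dists):
        if r > config.propensity_radius:
            continue
        p = table.lookup(atom.residue_name, atom.name, atom.element)[index]
        total += p * math.exp(sign * r / config.d0)
    return total


def hydrophilicity(
    site: WaterSite, model: StructureModel, table: PropensityTable, config: FeatureConfig | None = None
) -> float:
    """Σ h_i · exp(−r_i/d₀) over protein atoms within ``propensity_radius``."""
    return _propensity_sum(site, model, table, config or FeatureConfig(), index=0)


def hydrophobicity(
    site: WaterSite, model: StructureModel, table: PropensityTable, config: FeatureConfig | None = None
) -> float:
    """Σ l_i · exp(−r_i/d₀) over protein atoms within ``propensity_radius``."""
    return _propensity_sum(site, model, table, config or FeatureConfig(), index=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * math.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(site: WaterSite, model: StructureModel, config: FeatureConfig | None = None) -> float:
    """Solvent-accessible surface area (Å²) of the water-oxygen sphere.

    Shrake–Rupley: ``sasa_points`` test points are placed on the sphere of
    radius vdW(O) + probe around the oxygen; a point is buried when it lies
    inside the solvent-expanded sphere of any context atom.  By default the
    context is the protein only — other waters and the ligand do not
    occlude, so the feature reads as accessibility to bulk solvent.
    """
    config = config or FeatureConfig()
    radius = config.vdw("O") + config.probe_radius
    if config.sasa_context == "protein":
        context = model.protein_atoms
    else:
        context = [
            a for a in model.atoms
            if not (a.role == "water" and a.chain_id == site.chain_id and a.residue_number == site.residue_number)
        ]
    if not context:
        return 4.0 * math.pi * radius * radius

    ctx_xyz = np.array([a.position for a in context], dtype=float)
    ctx_r = np.array([config.vdw(a.element) for a in context]) + config.probe_radius
    # prune to atoms whose expanded sphere can reach the test sphere
    reach = np.linalg.norm(ctx_xyz - site.position, axis=1) <= radius + ctx_r
    ctx_xyz, ctx_r = ctx_xyz[reach], ctx_r[reach]
    points = site.position + radius * _fibonacci_sphere(config.sasa_points)
    if ctx_xyz.shape[0] == 0:
        accessible = config.sasa_points
    else:
        d2 = ((points[:, None, :] - ctx_xyz[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (ctx_r**2)[None, :]).any(axis=1)
        accessible = int((~buried).sum())
    return 4.0 * math.pi * radius * radius * accessible / config.sasa_points


def bfactor(site: WaterSite) -> float:
    """The water oxygen's temperature factor, verbatim from the coordinate file."""
    return float(site.b_factor)


def msd_to_bfactor(mean_displacement: float) -> float:
    """Convert a mean atomic displacement Ū (Å) to a B-factor: 8π²·Ū².

    Used when synthesising coordinate files; parsed B columns are taken
    verbatim, never re-derived.
    """
    return 8.0 * math.pi**2 * mean_displacement**2


def mobility(site: WaterSite, all_waters: list[WaterSite]) -> float:
    """Displacement degree relative to the water population of the structure.

    M = (BF_i / mean(BF)) / (O_i / mean(O)) with the means taken over the
    structure's water oxygens.  Stable waters have M < 1, mobile ones M > 1.
    """
    if not all_waters:
        raise ValueError("mobility needs at least one water for the normalisation baseline")
    bf = np.array([w.b_factor for w in all_waters], dtype=float)
    occ = np.array([w.occupancy for w in all_waters], dtype=float)
    if bf.mean() <= 0:
        raise ValueError("degenerate input: structure-mean water B-factor is zero")
    if occ.mean() <= 0 or site.occupancy <= 0:
        raise ValueError("degenerate input: zero occupancy in mobility normalisation")
    return float((site.b_factor / bf.mean()) / (site.occupancy / occ.mean()))


def featurize(
    site: WaterSite,
    model: StructureModel,
    table: PropensityTable | None = None,
    config: FeatureConfig | None = None,
    baseline_waters: list[WaterSite] | None = None,
) -> FeatureVector:
    """Assemble the six features A–F for one water site.

    *baseline_waters* overrides the mobility normalisation population
    (defaults to all water oxygens of *model*).
    """
    table = table or PropensityTable.default_table()
    config = config or FeatureConfig()
    waters = baseline_waters if baseline_waters is not None else water_sites(model)
    return FeatureVector(
        atom_density=atom_density(site, model, config),
        mobility=mobility(site, waters),
        bfactor=bfactor(site),
        hydrophilicity=hydrophilicity(site, model, table, config),
        hydrophobicity=hydrophobicity(site, model, table, config),
        sasa=sasa(site, model, config),
    )


def featurize_model(
    model: StructureModel,
    sites: list[WaterSite] | None = None,
    table: PropensityTable | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for every (or the given) water site of *model*.

    Columns: structure_id, chain, resnum, A…F, and label when sites carry
    one.
    """
    table = table or PropensityTable.default_table()
    config = config or FeatureConfig()
    all_waters = water_sites(model)
    if sites is None:
        sites = all_waters
    baseline = sites if config.mobility_scope == "pocket" else all_waters
    rows = []
    for s in sites:
        vec = featurize(s, model, table, config, baseline_waters=baseline)
        row = {"structure_id": s.source_id, "chain": s.chain_id, "resnum": s.residue_number}
        row.update(vec.as_dict())
        row["label"] = s.label
        rows.append(row)
    return pd.DataFrame(rows)
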