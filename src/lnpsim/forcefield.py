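"""Force-field parameter tables for the coarse-grain model.

The model uses five bead types: C1 (apolar), Na (intermediate polarity,
hydrogen-bond acceptor), P3 (polar), P4 (CG water, four real waters per
bead) and AF (antifreeze water bead, one per ten P4).  All nonbonded
interactions are 12-6 Lennard-Jones; bonded terms are harmonic bonds and
cosine-harmonic angles.  Parameter values live in a YAML config shipped
with the package (``data/martini_like.yaml``) and can be replaced by the
user; nothing numerical is hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

BEAD_TYPES = ("C1", "Na", "P3", "P4", "AF")


class ForceFieldError(ValueError):
    """Raised when a parameter file is missing entries or inconsistent."""


@dataclass(frozen=True)
class BondedDefaults:
    """Default bonded parameters shared by chain molecules."""

    bond_r0: float
    bond_k: float
    angle_theta0: float  # degrees
    angle_k: float
    ring_bond_r0: float
    ring_bond_k: float
    ring_constraint_k: float


@dataclass
class ForceFieldTables:
    """LJ pair table plus bonded defaults and water-model constants.

    ``lj`` maps unordered type pairs to ``(sigma, eps)``; the table is
    guaranteed symmetric by construction.  ``ring_sigma``/``ring_eps_scale``
    override pairs where both beads are fine-mapped ring beads.
    """

    lj: dict[tuple[str, str], tuple[float, float]]
    bonded: BondedDefaults
    ring_sigma: float
    ring_eps_scale: float
    af_per_p4_ratio: float = 0.1
    waters_per_p4: int = 4
    source: str = field(default="", compare=False)

    def pair(self, a: str, b: str, ring: bool = False) -> tuple[float, float]:
        """Return (sigma, eps) for a type pair; ring=True applies the
        fine-mapped override used between two ring beads."""
        sigma, eps = self.lj[(a, b)]
        if ring:
            return self.ring_sigma, eps * self.ring_eps_scale
        return sigma, eps

    def validate(self) -> None:
        for a in BEAD_TYPES:
            for b in BEAD_TYPES:
                if (a, b) not in self.lj:
                    raise ForceFieldError(f"missing LJ entry for pair ({a},{b})")
                if self.lj[(a, b)] != self.lj[(b, a)]:
                    raise ForceFieldError(f"asymmetric LJ table at ({a},{b})")
                sigma, eps = self.lj[(a, b)]
                if sigma <= 0 or eps <= 0:
                    raise ForceFieldError(
                        f"non-positive LJ parameters for ({a},{b}): {sigma}, {eps}"
                    )
        # Hydrophobic ordering: water-alkane attraction must be the weak
        # link, otherwise hydrophobic collapse cannot occur.
        e_c1_p4 = self.lj[("C1", "P4")][1]
        if not (e_c1_p4 < self.lj[("C1", "C1")][1] and e_c1_p4 < self.lj[("P4", "P4")][1]):
            raise ForceFieldError(
                "hydrophobic ordering violated: require eps(C1,P4) < eps(C1,C1) "
                "and eps(C1,P4) < eps(P4,P4)"
            )


def _default_config_path() -> Path:
    return Path(str(resources.files("lnpsim").joinpath("data/martini_like.yaml")))


def load_forcefield(path: str | Path | None = None) -> ForceFieldTables:
    """Load and validate a force-field parameter file.

    Parameters
    ----------
    path
        YAML parameter file; ``None`` loads the packaged default table.

    Raises
    ------
    ForceFieldError
        On missing pairs, asymmetric duplicate entries, non-positive
        parameters, or a violated hydrophobic ordering.
    """
    path = _default_config_path() if path is None else Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    lj: dict[tuple[str, str], tuple[float, float]] = {}
    for key, entry in cfg["lj"].items():
        a, b = key.split("-")
        if a not in BEAD_TYPES or b not in BEAD_TYPES:
            raise ForceFieldError(f"unknown bead type in pair key '{key}'")
        val = (float(entry["sigma"]), float(entry["eps"]))
        for pair in ((a, b), (b, a)):
            if pair in lj and lj[pair] != val:
                raise ForceFieldError(f"asymmetric LJ table: conflicting entry for {pair}")
            lj[pair] = val

    bonded_cfg = cfg["bonded"]
    bonded = BondedDefaults(
        bond_r0=float(bonded_cfg["bond"]["r0"]),
        bond_k=float(bonded_cfg["bond"]["k"]),
        angle_theta0=float(bonded_cfg["angle"]["theta0"]),
        angle_k=float(bonded_cfg["angle"]["k"]),
        ring_bond_r0=float(bonded_cfg["ring_bond"]["r0"]),
        ring_bond_k=float(bonded_cfg["ring_bond"]["k"]),
        ring_constraint_k=float(bonded_cfg["ring_constraint"]["k"]),
    )
    tables = ForceFieldTables(
        lj=lj,
        bonded=bonded,
        ring_sigma=float(cfg["ring"]["sigma"]),
        ring_eps_scale=float(cfg["ring"]["eps_scale"]),
        af_per_p4_ratio=float(cfg["water"]["af_per_p4_ratio"]),
        waters_per_p4=int(cfg["water"]["waters_per_p4"]),
        source=str(path),
    )
    tables.validate()
    return tables


def default_forcefield() -> ForceFieldTables:
    """The packaged Martini-2.0-like default table."""
    return load_forcefield(None)
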