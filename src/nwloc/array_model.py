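"""Nanowire array layouts and molecular ground truth.

A biosensing chip carries a near-square lattice of vertically aligned,
waveguiding nanowires (spacing ``p`` ≈ 0.99 µm).  A fraction of the lattice
sites hold defective wires — either missing entirely or kinked at a random
height — which do not enhance fluorescence.  Analyte molecules bind either
to a wire (at a discrete axial position along its length) or to the flat
substrate between wires.

This module generates such layouts and samples molecular ground truth with
the statistical structure used throughout the package's simulation studies:

* sites on a jittered square lattice, independently defective with a
  configurable probability (defaults to the 15 % defect rate observed by
  SEM on real arrays);
* a Poisson number of molecules per frame with mean ``c · A`` for surface
  concentration ``c`` and field area ``A``;
* wire/substrate partitioning proportional to available surface area,
  optionally biased by a capture-propensity ratio;
* axial binding positions on a 50 nm grid along the wire.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NanowireLayout",
    "GroundTruth",
    "generate_layout",
    "place_molecules",
    "DEFAULT_SPACING_UM",
    "DEFAULT_WIRE_LENGTH_UM",
    "AXIAL_STEP_UM",
]

#: Lattice spacing of the characterized arrays (µm).
DEFAULT_SPACING_UM = 0.99
#: Nanowire length (µm).
DEFAULT_WIRE_LENGTH_UM = 2.5
#: Axial discretization of binding sites along a wire (µm) — 50 nm steps.
AXIAL_STEP_UM = 0.05

#: Site status codes.
STATUS_STRAIGHT = "straight"
STATUS_KINKED = "kinked"
STATUS_MISSING = "missing"


@dataclass
class NanowireLayout:
    """Positions and status of every lattice site of a nanowire array.

    Coordinates are object-space µm with the origin at the field corner.
    ``kink_height_um`` is NaN for straight and missing sites.
    """

    positions_um: np.ndarray          # (n_sites, 2)
    status: np.ndarray                # (n_sites,) of {straight,kinked,missing}
    kink_height_um: np.ndarray        # (n_sites,)
    spacing_um: float = DEFAULT_SPACING_UM
    wire_length_um: float = DEFAULT_WIRE_LENGTH_UM
    d_top_nm: float = 114.41
    d_bot_nm: float = 122.41
    d_coat_nm: float = 10.48
    n_rows: int = 0
    n_cols: int = 0
    margin_um: float = field(default=0.0)

    @property
    def n_sites(self) -> int:
        return len(self.positions_um)

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the simulated field in µm."""
        return (
            self.n_cols * self.spacing_um + 2 * self.margin_um,
            self.n_rows * self.spacing_um + 2 * self.margin_um,
        )

    @property
    def field_area_um2(self) -> float:
        w, h = self.field_size_um
        return w * h

    @property
    def straight_mask(self) -> np.ndarray:
        return self.status == STATUS_STRAIGHT

    @property
    def density_all_per_um2(self) -> float:
        """Density of non-missing wires (SEM-style ρ)."""
        return float(np.sum(self.status != STATUS_MISSING)) / self.field_area_um2

    @property
    def density_straight_per_um2(self) -> float:
        """Density of straight, waveguiding wires (ρ_S)."""
        return float(np.sum(self.straight_mask)) / self.field_area_um2

    def wire_outer_diameter_um(self) -> float:
        """Mean outer diameter including the oxide coating (µm)."""
        return (0.5 * (self.d_top_nm + self.d_bot_nm) + 2.0 * self.d_coat_nm) / 1000.0

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write one row per site plus a JSON sidecar of lattice parameters."""
        path = Path(path)
        df = pd.DataFrame(
            {
                "site": np.arange(self.n_sites),
                "x_um": self.positions_um[:, 0],
                "y_um": self.positions_um[:, 1],
                "status": self.status,
                "kink_height_um": self.kink_height_um,
            }
        )
        with open(path, "w") as fh:
            fh.write(
                "# nanowire layout: one row per lattice site; coordinates in "
                "object-space um, origin at field corner\n"
            )
            df.to_csv(fh, index=False)
        sidecar = {
            "spacing_um": self.spacing_um,
            "wire_length_um": self.wire_length_um,
            "d_top_nm": self.d_top_nm,
            "d_bot_nm": self.d_bot_nm,
            "d_coat_nm": self.d_coat_nm,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "margin_um": self.margin_um,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NanowireLayout":
        path = Path(path)
        df = pd.read_csv(path, comment="#")
        params = json.loads(path.with_suffix(".json").read_text())
        return cls(
            positions_um=df[["x_um", "y_um"]].to_numpy(float),
            status=df["status"].to_numpy(str),
            kink_height_um=df["kink_height_um"].to_numpy(float),
            **params,
        )


@dataclass
class GroundTruth:
    """Per-molecule ground truth for one simulated frame.

    ``molecules`` has one row per molecule with columns

    ``x_um, y_um`` lateral position; ``z_um`` axial position (multiple of the
    50 nm step); ``target`` (``wire`` | ``substrate``); ``wire_index`` (site
    index, −1 for substrate molecules); ``enhanced`` (bool — couples to the
    waveguide); ``expected_photons`` (filled by the renderer).
    """

    molecules: pd.DataFrame
    surface_density_per_um2: float
    field_area_um2: float

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def bright_wires(self, layout: NanowireLayout) -> np.ndarray:
        """Indices of straight wires carrying at least one coupled molecule."""
        m = self.molecules
        idx = m.loc[(m["target"] == "wire") & m["enhanced"], "wire_index"]
        return np.unique(idx.to_numpy(int))

    def bright_wire_positions(self, layout: NanowireLayout) -> np.ndarray:
        """(k, 2) lateral positions (µm) of bright straight wires."""
        return layout.positions_um[self.bright_wires(layout)]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                "# molecular ground truth: one row per molecule; positions in um; "
                "z on the 50-nm axial grid; wire_index=-1 for substrate binding\n"
            )
            self.molecules.to_csv(fh, index=False)
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "surface_density_per_um2": self.surface_density_per_um2,
                    "field_area_um2": self.field_area_um2,
                }
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        path = Path(path)
        df = pd.read_csv(path, comment="#")
        params = json.loads(path.with_suffix(".json").read_text())
        return cls(molecules=df, **params)


def _validate_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def generate_layout(
    spacing_um: float = DEFAULT_SPACING_UM,
    n_rows: int = 20,
    n_cols: int = 20,
    defect_fraction: float = 0.15,
    jitter_sd_um: float = 0.02,
    seed: int | None = None,
    *,
    wire_length_um: float = DEFAULT_WIRE_LENGTH_UM,
    missing_fraction_of_defects: float = 0.5,
    max_kink_frac: float = 0.3,
    margin_um: float | None = None,
) -> NanowireLayout:
    """Generate a square nanowire lattice with random growth defects.

    Each site is independently defective with probability ``defect_fraction``;
    defective sites split between missing and kinked.  Kinks originate from
    perturbations early in epitaxial growth, so kink heights are drawn
    uniformly on the lower part of the wire, ``[0, max_kink_frac · L]``; the
    section above the kink bends away laterally and no longer waveguides.  A
    small Gaussian positional jitter models growth imperfection.
    ``margin_um`` pads the field around the lattice (defaults to half the
    spacing) so that edge wires have complete surroundings.
    """
    _validate_positive("spacing_um", spacing_um)
    _validate_positive("wire_length_um", wire_length_um)
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("n_rows and n_cols must be positive integers")
    if not 0.0 <= defect_fraction <= 1.0:
        raise ValueError("defect_fraction must lie in [0, 1]")
    if not 0.0 < max_kink_frac <= 1.0:
        raise ValueError("max_kink_frac must lie in (0, 1]")
    if jitter_sd_um < 0:
        raise ValueError("jitter_sd_um must be non-negative")
    if margin_um is None:
        margin_um = spacing_um / 2.0

    rng = np.random.default_rng(seed)
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = margin_um + (jj.ravel() + 0.5) * spacing_um
    y = margin_um + (ii.ravel() + 0.5) * spacing_um
    pos = np.column_stack([x, y])
    if jitter_sd_um > 0:
        pos = pos + rng.normal(0.0, jitter_sd_um, size=pos.shape)

    n = n_rows * n_cols
    status = np.full(n, STATUS_STRAIGHT, dtype=object)
    kink = np.full(n, np.nan)
    defective = rng.random(n) < defect_fraction
    missing = defective & (rng.random(n) < missing_fraction_of_defects)
    kinked = defective & ~missing
    status[missing] = STATUS_MISSING
    status[kinked] = STATUS_KINKED
    kink[kinked] = rng.uniform(
        0.0, max_kink_frac * wire_length_um, size=int(kinked.sum())
    )

    return NanowireLayout(
        positions_um=pos,
        status=status.astype(str),
        kink_height_um=kink,
        spacing_um=spacing_um,
        wire_length_um=wire_length_um,
        n_rows=n_rows,
        n_cols=n_cols,
        margin_um=margin_um,
    )


def _axial_grid(length_um: float, step_um: float = AXIAL_STEP_UM) -> np.ndarray:
    n = int(round(length_um / step_um))
    return np.arange(n + 1) * step_um


def place_molecules(
    layout: NanowireLayout,
    surface_density_per_um2: float,
    capture_bias: float = 1.0,
    seed: int | None = None,
    *,
    axial_step_um: float = AXIAL_STEP_UM,
    kinked_binding: str = "background",
) -> GroundTruth:
    """Sample molecular binding positions for one frame.

    The total count is Poisson with mean ``c · A``.  Each molecule is assigned
    to a wire or to the substrate with probability proportional to the
    respective surface area, with the wire side additionally weighted by
    ``capture_bias`` (1 = area-proportional; 0 = substrate only).  Wire-bound
    molecules land on a uniformly chosen non-missing wire at an axial position
    drawn from the 50 nm grid.

    ``kinked_binding`` controls molecules landing on kinked (defective) wires:

    * ``"background"`` (default): they remain at the site laterally but are
      flagged non-enhanced — defective wires do not waveguide, so these
      molecules only contribute defocused background;
    * ``"substrate"``: they are re-targeted to a uniform substrate position;
    * ``"exclude"``: kinked wires accept no molecules (only straight wires
      are selectable).
    """
    if layout.n_sites == 0:
        raise ValueError("layout has no sites")
    if surface_density_per_um2 < 0:
        raise ValueError("surface_density_per_um2 must be non-negative")
    if capture_bias < 0:
        raise ValueError("capture_bias must be non-negative")
    if kinked_binding not in ("background", "substrate", "exclude"):
        raise ValueError(f"unknown kinked_binding mode {kinked_binding!r}")

    rng = np.random.default_rng(seed)
    area = layout.field_area_um2
    n_total = int(rng.poisson(surface_density_per_um2 * area))

    # Area-proportional wire/substrate partition.  Wire side counts the lateral
    # surface of all standing (non-missing) wires; kinked wires still present
    # binding surface even though they do not enhance.
    standing = layout.status != STATUS_MISSING
    if kinked_binding == "exclude":
        bindable = layout.straight_mask
    else:
        bindable = standing
    wire_area_each = math.pi * layout.wire_outer_diameter_um() * layout.wire_length_um
    total_wire_area = wire_area_each * float(bindable.sum())
    p_wire = (
        capture_bias * total_wire_area / (capture_bias * total_wire_area + area)
        if (capture_bias > 0 and bindable.any())
        else 0.0
    )

    cols = [
        "x_um", "y_um", "z_um", "target", "wire_index", "enhanced",
        "expected_photons",
    ]
    if n_total == 0:
        mol = pd.DataFrame({c: [] for c in cols})
        mol = mol.astype({"wire_index": int, "enhanced": bool})
        return GroundTruth(mol, surface_density_per_um2, area)

    on_wire = rng.random(n_total) < p_wire
    n_wire = int(on_wire.sum())
    n_sub = n_total - n_wire
    w, h = layout.field_size_um

    records: dict[str, np.ndarray] = {}
    # substrate-bound molecules: uniform over the field, at z = 0
    sub_xy = rng.uniform([0, 0], [w, h], size=(n_sub, 2))

    bindable_idx = np.flatnonzero(bindable)
    wire_sites = rng.choice(bindable_idx, size=n_wire) if n_wire else np.empty(0, int)
    grid = _axial_grid(layout.wire_length_um, axial_step_um)
    z_wire = rng.choice(grid, size=n_wire) if n_wire else np.empty(0)
    enhanced = np.ones(n_wire, bool)
    x_wire = layout.positions_um[wire_sites, 0] if n_wire else np.empty(0)
    y_wire = layout.positions_um[wire_sites, 1] if n_wire else np.empty(0)
    target = np.full(n_wire, "wire", object)

    if n_wire:
        kinked_hit = layout.status[wire_sites] == STATUS_KINKED
        if kinked_binding == "background" and kinked_hit.any():
            # A kinked wire's section above the kink lies bent away nearly
            # horizontally at the kink height.  The sampled axial coordinate
            # is reinterpreted as arc length along the wire: below the kink
            # the molecule sits on the vertical stem at the site; above it,
            # it sits at the kink height, displaced laterally by the excess
            # arc length in a random direction.  Either way the emission is
            # unenhanced and strongly defocused (background contribution).
            kh = layout.kink_height_um[wire_sites[kinked_hit]]
            kh_grid = np.floor(kh / axial_step_um) * axial_step_um
            s = z_wire[kinked_hit]
            above = s > kh_grid
            excess = np.where(above, s - kh_grid, 0.0)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=int(kinked_hit.sum()))
            idx = np.flatnonzero(kinked_hit)
            x_wire[idx] = np.clip(x_wire[idx] + excess * np.cos(theta), 0.0, w)
            y_wire[idx] = np.clip(y_wire[idx] + excess * np.sin(theta), 0.0, h)
            z_wire[idx] = np.where(above, kh_grid, s)
            enhanced[kinked_hit] = False
        elif kinked_binding == "substrate" and kinked_hit.any():
            k = int(kinked_hit.sum())
            xy = rng.uniform([0, 0], [w, h], size=(k, 2))
            x_wire[kinked_hit] = xy[:, 0]
            y_wire[kinked_hit] = xy[:, 1]
            z_wire[kinked_hit] = 0.0
            enhanced[kinked_hit] = False
            target[kinked_hit] = "substrate"
            wire_sites = wire_sites.copy()
            wire_sites[kinked_hit] = -1

    records["x_um"] = np.concatenate([x_wire, sub_xy[:, 0]])
    records["y_um"] = np.concatenate([y_wire, sub_xy[:, 1]])
    records["z_um"] = np.concatenate([z_wire, np.zeros(n_sub)])
    records["target"] = np.concatenate([target, np.full(n_sub, "substrate", object)])
    records["wire_index"] = np.concatenate(
        [wire_sites, np.full(n_sub, -1)]
    ).astype(int)
    records["enhanced"] = np.concatenate([enhanced, np.zeros(n_sub, bool)])
    records["expected_photons"] = np.full(n_total, np.nan)

    mol = pd.DataFrame(records)
    return GroundTruth(mol, surface_density_per_um2, area)
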