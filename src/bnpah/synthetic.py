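"""Synthetic property tables with the qualitative structure of the DFT data.

The generator produces, per isomer, a HOMO-LUMO gap (eV), frontier-orbital
energies, a single-point energy (Hartree), a relative energy (kcal/mol) and
auxiliary columns, as closed-form functions of the six feature components
plus Gaussian noise.  The functional forms encode the trends the DFT space
exhibits:

* the gap falls with ring count, linear-stretch length and the number of
  disrupted rings, with ``n_DR`` carrying the dominant coefficient;
* the gap falls with B-N separation as amplitude/(n_SP + 1) — the
  polyene-like 1/n shape — with a small odd/even parity zigzag;
* both-outer placements sit slightly below both-inner placements in gap;
* the relative energy rises with ``n_SP`` and ``n_DR`` and drops sharply
  when B and N share a bond (electrostatic stabilization of the B-N unit),
  and is shifted so each ring-count group has an exact zero minimum.

None of this mimics DFT quantitatively; it gives downstream statistics and
models a target surface with known ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

#: kcal/mol per Hartree.
HARTREE_TO_KCAL = 627.5095

PROPERTY_COLUMNS = [
    "molecule_id",
    "homo",
    "lumo",
    "gap",
    "spe",
    "e_rel",
    "aip",
    "aea",
    "dipole",
    "imaginary_flag",
]


@dataclass(frozen=True)
class SyntheticModelConfig:
    """Coefficients of the synthetic property surface.

    Gap terms are in eV, relative-energy terms in kcal/mol.  The sign of
    ``erel_DR_coef`` is deliberately a plain config knob: disruption of
    aromatic stabilization argues for destabilization (positive), and the
    default follows that reading.
    """

    gap_intercept: float = 7.2
    gap_ring_coef: float = -0.18
    gap_LL_coef: float = -0.10
    gap_DR_coef: float = -0.45  # dominant feature by construction
    gap_SP_amplitude: float = 1.2
    gap_SP_offset: float = 1.0
    gap_parity_coef: float = 0.12  # added for odd n_SP (zigzag)
    inner_outer_offsets: tuple[float, float, float, float] = (
        -0.06,  # (b_outer, n_outer): lowest gaps
        0.0,  # (b_outer, n_inner)
        0.0,  # (b_inner, n_outer)
        0.06,  # (b_inner, n_inner): highest gaps
    )
    erel_SP_coef: float = 1.6
    erel_DR_coef: float = 3.5
    erel_bonded_bonus: float = 12.0  # extra stabilization at n_SP = 0
    erel_inner_outer_offsets: tuple[float, float, float, float] = (
        -1.0,  # BoNo
        3.0,  # BoNi: least stable
        -3.0,  # BiNo: most stable
        -2.0,  # BiNi
    )
    noise_sd_gap: float = 0.12
    noise_sd_erel: float = 2.0
    imaginary_fraction: float = 0.066
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_gap < 0 or self.noise_sd_erel < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.gap_SP_offset <= 0:
            raise ValueError("gap_SP_offset must be positive")


def _io_index(b_inner: np.ndarray, n_inner: np.ndarray) -> np.ndarray:
    return 2 * b_inner + n_inner


def gap_surface(features: pd.DataFrame, config: SyntheticModelConfig) -> np.ndarray:
    """Noise-free HOMO-LUMO gap surface (eV) over a feature table."""
    io = np.asarray(config.inner_outer_offsets)[
        _io_index(features["b_inner"].to_numpy(), features["n_inner"].to_numpy())
    ]
    n_sp = features["n_SP"].to_numpy()
    gap = (
        config.gap_intercept
        + config.gap_ring_coef * features["n_rings"].to_numpy()
        + config.gap_LL_coef * features["n_LL"].to_numpy()
        + config.gap_DR_coef * features["n_DR"].to_numpy()
        + config.gap_SP_amplitude / (n_sp + config.gap_SP_offset)
        + config.gap_parity_coef * (n_sp % 2)
        + io
    )
    return gap


def erel_surface(features: pd.DataFrame, config: SyntheticModelConfig) -> np.ndarray:
    """Noise-free relative-energy surface (kcal/mol), before group shifting."""
    io = np.asarray(config.erel_inner_outer_offsets)[
        _io_index(features["b_inner"].to_numpy(), features["n_inner"].to_numpy())
    ]
    n_sp = features["n_SP"].to_numpy()
    return (
        config.erel_SP_coef * n_sp
        + config.erel_DR_coef * features["n_DR"].to_numpy()
        - config.erel_bonded_bonus * (n_sp == 0)
        + io
    )


def generate_properties(
    features: pd.DataFrame, config: SyntheticModelConfig | None = None
) -> pd.DataFrame:
    """Synthesize a full property table for a feature table.

    Requires the six feature columns plus ``molecule_id`` and ``n_rings``.
    Fully reproducible from ``config.seed``; with both noise terms at zero
    the output equals the closed-form surfaces exactly.
    """
    if len(features) == 0:
        raise ValueError("empty isomer list")
    if config is None:
        config = SyntheticModelConfig()
    rng = np.random.default_rng(config.seed)

    gap = gap_surface(features, config)
    gap = np.clip(gap + rng.normal(0.0, config.noise_sd_gap, len(features)), 0.0, None)

    e_raw = erel_surface(features, config)
    e_raw = e_raw + rng.normal(0.0, config.noise_sd_erel, len(features))
    n_rings = features["n_rings"].to_numpy()
    e_rel = np.empty_like(e_raw)
    for n in np.unique(n_rings):
        mask = n_rings == n
        e_rel[mask] = e_raw[mask] - e_raw[mask].min()

    # frontier orbitals centered at -3.5 eV so gap == lumo - homo exactly
    homo = -3.5 - gap / 2.0
    lumo = -3.5 + gap / 2.0
    # SPE in Hartree: a per-size baseline plus the relative energy
    spe = -153.0 * n_rings + e_rel / HARTREE_TO_KCAL
    aip = 6.8 - 0.15 * n_rings - 0.05 * features["n_DR"].to_numpy() + rng.normal(
        0.0, 0.05, len(features)
    )
    aea = 0.3 + 0.12 * n_rings + 0.04 * features["n_DR"].to_numpy() + rng.normal(
        0.0, 0.05, len(features)
    )
    dipole = np.abs(
        0.8 + 0.45 * features["n_SP"].to_numpy() + rng.normal(0.0, 0.2, len(features))
    )
    imaginary = rng.random(len(features)) < config.imaginary_fraction

    out = pd.DataFrame(
        {
            "molecule_id": features["molecule_id"].to_numpy(),
            "homo": homo,
            "lumo": lumo,
            "gap": gap,
            "spe": spe,
            "e_rel": e_rel,
            "aip": aip,
            "aea": aea,
            "dipole": dipole,
            "imaginary_flag": imaginary,
        }
    )
    return out


class PropertyFormatError(ValueError):
    """Raised when a property table violates the schema."""


def load_properties(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a property table CSV.

    Checks the column schema, gap = lumo - homo consistency (warning beyond
    1e-6 eV) and non-negativity of ``e_rel`` (error).
    """
    import warnings

    df = pd.read_csv(path)
    missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise PropertyFormatError(f"missing columns: {missing}")
    resid = np.abs((df["lumo"] - df["homo"]) - df["gap"])
    if (resid > 1e-6).any():
        warnings.warn(
            f"{int((resid > 1e-6).sum())} records violate gap = lumo - homo",
            stacklevel=2,
        )
    if (df["e_rel"] < 0).any():
        raise PropertyFormatError("negative e_rel values present")
    return df


def save_properties(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def config_to_json(config: SyntheticModelConfig) -> dict:
    return asdict(config)


def config_from_json(data: dict) -> SyntheticModelConfig:
    data = dict(data)
    for key in ("inner_outer_offsets", "erel_inner_outer_offsets"):
        if key in data:
            data[key] = tuple(data[key])
    return SyntheticModelConfig(**data)
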