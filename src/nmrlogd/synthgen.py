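"""Synthetic data with known structure for the full pipeline.

Real studies of this kind rest on a measured compound library: hundreds
of drug-like molecules with assigned ¹H shifts, recorded spectra, and
chromatographic logD labels at pH 2.6 / 7.4 / 10.5.  This module emulates
that world at desk scale with a planted, fully known dependence between
spectral features and labels:

* a **compound** is a multiset of proton environment groups (methyl,
  methylene, aromatic, ...); each group draws one shared chemical shift
  from its class distribution — mirroring how equivalent protons resonate
  together and carry relative integration;
* **labels** are a linear function of the bucketized feature vector,
  rescaled per (parameter, pH) slice to the mean/SD of the corresponding
  real label distributions, plus Gaussian noise;
* **traces** are sums of unit-area Lorentzian lines (one per proton) on
  a dense grid with Gaussian baseline noise, standing in for
  experimental-style spectra;
* a separate **HOSE world** of small real molecular graphs (alkanes,
  aromatics, ethers, ...) with rule-based reference shifts feeds the
  HOSE-code predictor's training and fallback tests.

Everything is bit-reproducible under the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import (SOURCE_EXPERIMENTAL, SOURCE_HOSE, DataError, ShiftList,
                     SpectrumTrace)
from .spectra import (DEFAULT_N_BINS, DEFAULT_PPM_MAX, DEFAULT_PPM_MIN,
                      TRACE_POINTS, TRACE_PPM_MAX, TRACE_PPM_MIN, bucketize)

logger = logging.getLogger("nmrlogd")

#: Proton environment classes: class -> (shift ppm, per-occurrence SD ppm).
#: Positions follow the standard ¹H correlation chart.  The default SD is
#: 0 because the library emulates *predictor-generated* pseudo-spectra: a
#: lookup-table shift predictor returns the same tabulated value for every
#: occurrence of an environment, exactly as a HOSE-table prediction does.
#: Set the SDs > 0 to emulate DFT-style lists (distinct per-proton shifts)
#: or experimental assignment scatter.
DEFAULT_PALETTE: dict[str, tuple[float, float]] = {
    "methyl_alkyl": (0.90, 0.0),
    "methylene_alkyl": (1.30, 0.0),
    "methine_alkyl": (1.70, 0.0),
    "allylic_or_alpha_carbonyl": (2.20, 0.0),
    "n_methyl": (2.90, 0.0),
    "o_methyl": (3.70, 0.0),
    "o_methylene": (4.10, 0.0),
    "vinyl": (5.50, 0.0),
    "aromatic": (7.30, 0.0),
    "amide_nh": (8.10, 0.0),
    "aldehyde": (9.80, 0.0),
}

#: Real-world label statistics per (parameter, pH): mean and SD of the
#: chromatographic logD distributions the generator emulates.
DEFAULT_LABEL_STATS: dict[tuple[str, float], tuple[float, float]] = {
    ("CHI", 2.6): (0.94, 1.29),
    ("CHI", 7.4): (2.21, 1.03),
    ("CHI", 10.5): (2.42, 1.27),
    ("Chrom", 2.6): (2.33, 2.29),
    ("Chrom", 7.4): (4.14, 1.82),
    ("Chrom", 10.5): (4.34, 2.17),
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic library; defaults define the study conditions."""

    n_compounds: int = 300
    protons_range: tuple[int, int] = (6, 30)
    palette: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))
    trace_linewidth: float = 0.01       # Lorentzian FWHM, ppm
    trace_noise_sd: float = 0.02        # baseline noise vs unit-area peaks
    label_noise_rel: float = 0.3        # label noise SD as fraction of signal SD
    label_weights: np.ndarray | None = None   # per-bin weights; None = per-class
    label_stats: dict[tuple[str, float], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_STATS))
    n_bins: int = DEFAULT_N_BINS
    ppm_min: float = DEFAULT_PPM_MIN
    ppm_max: float = DEFAULT_PPM_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.palette:
            raise DataError("environment class palette must be non-empty")
        for name, (mean, sd) in self.palette.items():
            if sd < 0:
                raise DataError(f"palette class {name!r}: negative SD")
            if not self.ppm_min <= mean < self.ppm_max:
                raise DataError(f"palette class {name!r}: mean {mean} outside "
                                f"[{self.ppm_min}, {self.ppm_max})")
        if self.label_noise_rel < 0 or self.trace_noise_sd < 0:
            raise DataError("noise SDs must be >= 0")

    def expected_label_sd(self, parameter: str, ph: float) -> float:
        """SD the label model implies: signal SD inflated by the noise term."""
        _, sd = self.label_stats[(parameter, ph)]
        return sd * float(np.sqrt(1.0 + self.label_noise_rel ** 2))


@dataclass
class SyntheticCompound:
    """A molecule abstracted to its proton-environment groups."""

    compound_id: str
    groups: list[tuple[str, int]]     # (environment class, #protons)

    @property
    def n_protons(self) -> int:
        return sum(n for _, n in self.groups)


def generate_library(cfg: SynthConfig
                     ) -> tuple[list[SyntheticCompound], list[ShiftList],
                                pd.DataFrame]:
    """Draw compounds, per-proton shifts, and logD labels with planted signal.

    Each compound accumulates environment groups (group sizes 1-3,
    methyl-heavy, as in organic molecules) until its proton budget is
    spent; every group shares one shift drawn from its class.  Labels for
    each (parameter, pH) slice are a linear read-out of the bucketized
    features — by default with piecewise-per-class weights (each bin
    weighted by the coefficient of the nearest environment class), i.e.
    logD is driven by the compound's proton-class composition, the way
    lipophilicity tracks aliphatic vs polar vs aromatic proton content —
    standardized across the library and rescaled to that slice's target
    mean/SD, plus Gaussian noise of ``label_noise_rel`` × signal SD.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.palette)
    compounds: list[SyntheticCompound] = []
    shift_lists: list[ShiftList] = []
    lo, hi = cfg.protons_range
    for i in range(cfg.n_compounds):
        cid = f"syn_{i:04d}"
        budget = int(rng.integers(lo, hi + 1))
        groups: list[tuple[str, int]] = []
        shifts: list[float] = []
        while budget > 0:
            cls = classes[rng.integers(len(classes))]
            size = min(budget, int(rng.choice([1, 2, 2, 3, 3])))
            mean, sd = cfg.palette[cls]
            shift = float(rng.normal(mean, sd))
            groups.append((cls, size))
            shifts.extend([shift] * size)
            budget -= size
        compounds.append(SyntheticCompound(compound_id=cid, groups=groups))
        shift_lists.append(ShiftList(compound_id=cid, shifts=np.array(shifts),
                                     source=SOURCE_HOSE))

    X = np.vstack([bucketize(sl, cfg.n_bins, cfg.ppm_min, cfg.ppm_max).counts
                   for sl in shift_lists]).astype(float)

    edges = np.linspace(cfg.ppm_min, cfg.ppm_max, cfg.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    class_means = np.array([cfg.palette[c][0] for c in classes])
    nearest_class = np.argmin(np.abs(centers[:, None] - class_means[None, :]),
                              axis=1)
    rows = []
    for k, ((parameter, ph), (mean_t, sd_t)) in enumerate(
            sorted(cfg.label_stats.items())):
        slice_rng = np.random.default_rng((cfg.seed, 1000 + k))
        if cfg.label_weights is not None:
            w = np.asarray(cfg.label_weights, dtype=float)
        else:
            beta = slice_rng.normal(size=len(classes))
            w = beta[nearest_class]
        signal = X @ w
        spread = signal.std(ddof=0)
        if spread == 0:
            raise DataError("degenerate library: zero signal spread")
        z = (signal - signal.mean()) / spread
        noise = slice_rng.normal(0.0, cfg.label_noise_rel * sd_t,
                                 size=cfg.n_compounds)
        y = mean_t + sd_t * z + noise
        for sl, value in zip(shift_lists, y):
            rows.append({"compound_id": sl.compound_id, "parameter": parameter,
                         "pH": ph, "value": float(value)})
    labels = pd.DataFrame(rows)
    return compounds, shift_lists, labels


def generate_trace(shifts: ShiftList, linewidth: float = 0.01,
                   noise_sd: float = 0.02, grid: np.ndarray | None = None,
                   seed: int = 0) -> SpectrumTrace:
    """Experimental-style trace: unit-area Lorentzians plus baseline noise.

    One Lorentzian of FWHM ``linewidth`` (ppm) per proton, centred at its
    shift, evaluated on ``grid`` (default: the standard 16,384-point grid
    over [-1, 12] ppm); Gaussian noise of SD ``noise_sd`` is added on top.
    """
    if linewidth <= 0:
        raise DataError("linewidth must be positive")
    if grid is None:
        grid = np.linspace(TRACE_PPM_MIN, TRACE_PPM_MAX, TRACE_POINTS)
    gamma = linewidth / 2.0     # half width at half maximum
    intensity = np.zeros_like(grid, dtype=float)
    for x0 in shifts.shifts:
        intensity += (gamma / np.pi) / ((grid - x0) ** 2 + gamma ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng((seed, hash_id(shifts.compound_id)))
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    return SpectrumTrace(ppm=grid, intensity=intensity,
                         compound_id=shifts.compound_id)


def hash_id(compound_id: str) -> int:
    """Stable non-negative integer from a compound id (for seed derivation)."""
    import hashlib

    digest = hashlib.blake2b(compound_id.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


# ---------------------------------------------------------------------------
# HOSE world: small real molecular graphs with rule-based reference shifts.

DEFAULT_TRAINING_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("CC", "ethane"),
    ("CCC", "propane"),
    ("CCCC", "butane"),
    ("CCCCC", "pentane"),
    ("CC(C)C", "isobutane"),
    ("c1ccccc1", "benzene"),
    ("Cc1ccccc1", "toluene"),
    ("CC(C)=O", "acetone"),
    ("CO", "methanol"),
    ("CCO", "ethanol"),
    ("CCOCC", "diethyl_ether"),
    ("COc1ccccc1", "anisole"),
    ("Cc1ccc(C)cc1", "p_xylene"),
    ("CC=O", "acetaldehyde"),
)

DEFAULT_HELDOUT_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("CCCCCC", "hexane"),
    ("CCc1ccccc1", "ethylbenzene"),
    ("CCOC", "ethyl_methyl_ether"),
)


def reference_shift(atom: Chem.Atom) -> float:
    """Rule-based ¹H shift (ppm) for the hydrogens on one heavy atom.

    A coarse correlation chart: enough structure for the HOSE predictor to
    have something consistent to learn, not a real shift model.
    """
    nh = atom.GetTotalNumHs(includeNeighbors=True)
    if atom.GetAtomicNum() == 8:
        return 2.50                                   # hydroxyl
    if atom.GetAtomicNum() == 7:
        return 1.80                                   # amine
    if atom.GetIsAromatic():
        return 7.26
    nbrs = list(atom.GetNeighbors())
    has_carbonyl_nbr = any(
        n.GetAtomicNum() == 6 and any(
            b.GetBondType() == Chem.BondType.DOUBLE and
            b.GetOtherAtom(n).GetAtomicNum() == 8 for b in n.GetBonds())
        for n in nbrs)
    is_carbonyl = any(b.GetBondType() == Chem.BondType.DOUBLE and
                      b.GetOtherAtom(atom).GetAtomicNum() == 8
                      for b in atom.GetBonds())
    if is_carbonyl:
        return 9.80                                   # aldehyde CH
    if any(n.GetAtomicNum() == 8 for n in nbrs):
        return {3: 3.30, 2: 3.40}.get(nh, 3.60)       # O-CH3 / O-CH2 / O-CH
    if has_carbonyl_nbr:
        return 2.10                                   # alpha to carbonyl
    if any(n.GetIsAromatic() for n in nbrs):
        return 2.30                                   # benzylic
    if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
        return 5.40                                   # vinyl
    return {3: 0.90, 2: 1.30}.get(nh, 1.70)           # plain alkyl


def molecule_with_shifts(smiles: str, name: str, jitter_sd: float = 0.0,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Chem.Mol, ShiftList]:
    """Parse one template and attach a mapped rule-based shift list."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"bad template SMILES {smiles!r}")
    mol.SetProp("_Name", name)
    shifts: list[float] = []
    h_indices: list[int] = []
    for atom in mol.GetAtoms():
        nh = atom.GetTotalNumHs(includeNeighbors=True)
        if nh == 0:
            continue
        value = reference_shift(atom)
        if jitter_sd > 0 and rng is not None:
            value += float(rng.normal(0.0, jitter_sd))
        shifts.extend([value] * nh)
        h_indices.extend([atom.GetIdx()] * nh)
    sl = ShiftList(compound_id=name, shifts=np.array(shifts),
                   h_indices=h_indices, source=SOURCE_EXPERIMENTAL)
    return mol, sl


def generate_hose_world(templates: tuple[tuple[str, str], ...] | None = None,
                        held_out: tuple[tuple[str, str], ...] | None = None,
                        jitter_sd: float = 0.0, seed: int = 0
                        ) -> tuple[list[tuple[Chem.Mol, ShiftList]],
                                   list[Chem.Mol]]:
    """Small molecular graphs with mapped shifts, plus held-out molecules.

    The training half feeds ``hose_shift.build_table``; the held-out
    molecules exercise sphere-by-sphere fallback on environments absent
    from training.  ``jitter_sd`` adds per-anchor Gaussian scatter around
    the rule-based class shifts.
    """
    if templates is None:
        templates = DEFAULT_TRAINING_TEMPLATES
    if held_out is None:
        held_out = DEFAULT_HELDOUT_TEMPLATES
    if not templates:
        raise DataError("empty template list")
    rng = np.random.default_rng(seed)
    training = [molecule_with_shifts(smi, name, jitter_sd, rng)
                for smi, name in templates]
    held: list[Chem.Mol] = []
    for smi, name in held_out:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DataError(f"bad held-out SMILES {smi!r}")
        mol.SetProp("_Name", name)
        held.append(mol)
    return training, held
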