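"""Study orchestration: source comparison, mixing, domain, similarity.

Four study designs around the CV machinery in :mod:`nmrlogd.mlmodel`:

* **source comparison** — one 10CV report per spectrum source (DFT-style,
  HOSE-predicted, trace-derived, experimental ...) on the same compounds
  and labels, plus the hashed-label negative control;
* **dataset mixing** — replace the feature vectors of a seeded random
  subset of compounds with those from a second (generated) source and
  follow cross-validated RMSE as the generated fraction grows;
* **applicability-domain profiling** — absolute out-of-fold error as a
  function of the true label value, with extreme-tail flags (errors
  concentrate at the sparsely populated ends of the label range);
* **training-set similarity** — ECFP4/Tanimoto similarity of external
  compounds to the training library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemio import DataError, compound_id
from .mlmodel import Dataset, EvalReport, cross_validate_10cv, hashed_label_control

logger = logging.getLogger("nmrlogd")


@dataclass
class MixingPlan:
    """Fractions of generated spectra to blend in, with seeded repeats."""

    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    repeats: int = 10
    source: str = "generated"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def run_source_comparison(sources: dict[str, Dataset], params: dict | None = None,
                          seed: int = 0,
                          include_control: bool = True) -> pd.DataFrame:
    """10CV every spectrum source on shared compounds/labels; rank by RMSE.

    All datasets must agree on compound ids and label values.  A
    hashed-label negative control derived from the first source is
    appended unless disabled.  Returns one row per source with the main
    CV metrics, flagging the best and worst RMSE.
    """
    if not sources:
        raise DataError("no sources given")
    items = list(sources.items())
    ref_ids, ref_y = items[0][1].compound_ids, items[0][1].y
    for tag, ds in items[1:]:
        if ds.compound_ids != ref_ids:
            raise DataError(f"source {tag!r}: compound ids differ from "
                            f"{items[0][0]!r}")
        if not np.allclose(ds.y, ref_y):
            raise DataError(f"source {tag!r}: labels differ from {items[0][0]!r}")
    reports: dict[str, EvalReport] = {}
    for tag, ds in items:
        reports[tag] = cross_validate_10cv(ds, params=params, seed=seed)
    if include_control:
        control = hashed_label_control(items[0][1], seed=seed)
        reports["hashed_control"] = cross_validate_10cv(control, params=params,
                                                        seed=seed)
    rows = []
    for tag, rep in reports.items():
        rows.append({"source": tag, "rmse": rep.rmse, "nrmse_mean": rep.nrmse_mean,
                     "nrmse_range": rep.nrmse_range, "nrmse_sd": rep.nrmse_sd,
                     "mae_mean": rep.mae_mean, "mae_median": rep.mae_median,
                     "seed": rep.seed})
    table = pd.DataFrame(rows).set_index("source")
    table["best"] = table["rmse"] == table["rmse"].min()
    table["worst"] = table["rmse"] == table["rmse"].max()
    table.attrs["reports"] = reports
    return table


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mix_datasets(exp: Dataset, gen: Dataset, fraction: float,
                 seed: int = 0) -> Dataset:
    """Swap a seeded random subset of feature rows from ``exp`` to ``gen``.

    Compound identity and labels are fixed; exactly
    round(fraction · n) compounds (half rounded away from zero) take
    their feature vector from the generated source, the rest keep the
    experimental one.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DataError(f"fraction {fraction} outside [0, 1]")
    if exp.compound_ids != gen.compound_ids:
        raise DataError("mix_datasets: compound ids differ between sources")
    if not np.allclose(exp.y, gen.y):
        raise DataError("mix_datasets: labels differ between sources")
    n = len(exp)
    k = _round_half_away(fraction * n)
    rng = np.random.default_rng(int(seed))
    take_gen = rng.choice(n, size=k, replace=False)
    X = exp.X.copy()
    X[take_gen] = gen.X[take_gen]
    return Dataset(X=X, y=exp.y.copy(), compound_ids=list(exp.compound_ids),
                   source=f"mix_{exp.source}_{gen.source}_{fraction:.2f}")


def run_mixing_experiment(exp: Dataset, gen: Dataset, plan: MixingPlan,
                          params: dict | None = None) -> pd.DataFrame:
    """Mean ± SD of pooled 10CV RMSE per generated-spectrum fraction.

    The endpoints 0 (pure experimental) and 1 (pure generated) are always
    included.  For repeat *r* both the mixing subset and the CV fold
    shuffle use seed ``base_seed + r``, so the fraction-0 and fraction-1
    rows reproduce the corresponding pure-source CV runs bit-exactly.
    """
    fractions = sorted(set((0.0, *plan.fractions, 1.0)))
    rows = []
    for frac in fractions:
        rmses = []
        for r in range(plan.repeats):
            seed = plan.base_seed + r
            mixed = mix_datasets(exp, gen, frac, seed=seed)
            rep = cross_validate_10cv(mixed, params=params, seed=seed)
            rmses.append(rep.rmse)
        rows.append({"fraction": frac, "mean_rmse": float(np.mean(rmses)),
                     "sd_rmse": float(np.std(rmses, ddof=1)) if len(rmses) > 1 else 0.0,
                     "n_repeats": plan.repeats,
                     "rmses": rmses})
    return pd.DataFrame(rows)


def error_vs_value_profile(report: EvalReport, n_value_bins: int = 10,
                           tail_quantile: float = 0.05) -> pd.DataFrame:
    """Absolute out-of-fold error as a function of the true label value.

    Returns one row per compound, sorted by true value, with the binned
    mean error attached and compounds in the extreme ``tail_quantile``
    tails of the label distribution flagged.  Models typically predict
    worst near the boundaries of the label range, where training examples
    are sparse.
    """
    preds = report.predictions
    df = pd.DataFrame({
        "compound_id": preds["compound_id"],
        "y_true": preds["y_true"],
        "abs_error": np.abs(preds["y_pred"] - preds["y_true"]),
    }).sort_values("y_true").reset_index(drop=True)
    lo = df["y_true"].quantile(tail_quantile)
    hi = df["y_true"].quantile(1 - tail_quantile)
    df["tail"] = (df["y_true"] <= lo) | (df["y_true"] >= hi)
    bins = pd.cut(df["y_true"], bins=n_value_bins, include_lowest=True)
    df["value_bin"] = bins
    df["bin_mean_error"] = df.groupby("value_bin", observed=True)["abs_error"] \
                             .transform("mean")
    return df


@dataclass
class SimilarityReport:
    """ECFP4/Tanimoto similarity of external compounds to a training set."""

    matrix: pd.DataFrame           # external ids × training ids
    per_compound: pd.DataFrame = field(init=False)  # mean/max per external id
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_compound = pd.DataFrame({
            "mean_similarity": self.matrix.mean(axis=1),
            "max_similarity": self.matrix.max(axis=1),
        })
        values = self.matrix.to_numpy().ravel()
        self.mean = float(values.mean())
        self.sd = float(values.std(ddof=0))


def tanimoto_similarity(external: list[Chem.Mol], training: list[Chem.Mol],
                        radius: int = 2, n_bits: int = 2048) -> SimilarityReport:
    """Full Tanimoto matrix on circular (ECFP4-style) fingerprints.

    Fingerprints are Morgan bit vectors of the given radius (radius 2 =
    diameter 4, i.e. ECFP4) folded to ``n_bits``; Tanimoto(A, B) =
    |A∩B| / |A∪B| on the bit sets.  Molecules whose fingerprint cannot be
    computed are skipped with a warning.
    """
    if not external or not training:
        raise DataError("both compound sets must be non-empty")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)

    def fps(mols):
        out, ids = [], []
        for i, mol in enumerate(mols):
            try:
                out.append(gen.GetFingerprint(mol))
                ids.append(compound_id(mol) or f"cmpd_{i}")
            except Exception as err:  # noqa: BLE001 - skip-and-log contract
                logger.warning("fingerprint failed for %s: %s",
                               compound_id(mol) or f"cmpd_{i}", err)
        return out, ids

    ext_fps, ext_ids = fps(external)
    trn_fps, trn_ids = fps(training)
    if not ext_fps or not trn_fps:
        raise DataError("no fingerprints could be computed")
    rows = [DataStructs.BulkTanimotoSimilarity(fp, trn_fps) for fp in ext_fps]
    matrix = pd.DataFrame(rows, index=ext_ids, columns=trn_ids)
    return SimilarityReport(matrix=matrix)
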