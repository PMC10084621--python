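"""Growth-rate derivation, trait transformations and the collinearity screen.

Growth rates are ratios of final size to development time: GRM = mass /
dev_time (mg/day) and GRH = head_width / dev_time (mm/day). Head width and
wing pad length are log-transformed; the growth rates are arcsine-transformed
(applied to the raw ratio, which must lie in [0, 1]); mass and development
time enter the analysis untransformed. Highly collinear traits are removed by
a Spearman rank-correlation screen before canonical correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

#: default transform per trait; mass and dev_time are deliberately untransformed
DEFAULT_TRANSFORMS = {
    "mass": "none",
    "head_width": "log",
    "wing_pad": "log",
    "dev_time": "none",
    "grm": "arcsin",
    "grh": "arcsin",
}


@dataclass
class TraitConfig:
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    spearman_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.spearman_threshold <= 1.0):
            raise ValueError("spearman_threshold must be in (0, 1]")
        bad = set(self.transforms.values()) - {"none", "log", "arcsin"}
        if bad:
            raise ValueError(f"unknown transform(s): {bad}")


def derive_growth_rates(pheno: pd.DataFrame) -> pd.DataFrame:
    """Append grm = mass/dev_time and grh = head_width/dev_time."""
    if (pheno["dev_time"] == 0).any():
        raise ValidationError("dev_time of 0 days: growth rate undefined")
    out = pheno.copy()
    out["grm"] = out["mass"] / out["dev_time"]
    out["grh"] = out["head_width"] / out["dev_time"]
    return out


def transform_traits(pheno: pd.DataFrame, cfg: TraitConfig | None = None) -> pd.DataFrame:
    """Build the analysis-scale trait matrix (rows indexed by individual_id).

    Raises on domain violations: log of a non-positive value, arcsine of a
    value outside [0, 1].
    """
    cfg = cfg or TraitConfig()
    out = {}
    for trait, transform in cfg.transforms.items():
        if trait not in pheno.columns:
            raise ValidationError(f"trait {trait!r} named in TraitConfig is absent")
        vals = pheno[trait].to_numpy(dtype=float)
        if transform == "log":
            if (vals <= 0).any():
                row = int(np.flatnonzero(vals <= 0)[0])
                raise ValidationError(f"log transform of {trait!r}: non-positive value at row {row}")
            out[trait] = np.log(vals)
        elif transform == "arcsin":
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"arcsine transform of {trait!r}: value {vals[row]:.4g} at row {row} "
                    "outside [0, 1]; rescale the trait first"
                )
            out[trait] = np.arcsin(vals)
        else:
            out[trait] = vals
    tm = pd.DataFrame(out, index=pd.Index(pheno["individual_id"], name="individual_id"))
    if not np.isfinite(tm.to_numpy()).all():
        raise ValidationError("non-finite value in transformed trait matrix")
    return tm


def spearman_matrix(tm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (symmetric, unit diagonal)."""
    if (tm.nunique() <= 1).any():
        col = tm.columns[(tm.nunique() <= 1).argmax()]
        raise ValidationError(f"column {col!r} is constant; rank correlation undefined")
    rho = stats.spearmanr(tm.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=tm.columns, columns=tm.columns)


def collinearity_screen(
    tm: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Iteratively drop collinear traits.

    While any off-diagonal |Spearman r| exceeds ``threshold`` (strictly; at a
    threshold of exactly 1.0 the comparison becomes >=), drop — among the
    traits involved in an offending pair — the one with the largest mean |r|
    against all remaining traits, breaking ties alphabetically. Returns the
    retained matrix, the dropped names in drop order, and the full correlation
    table computed before any drop.
    """
    if tm.shape[1] < 2 or tm.shape[0] < 3:
        raise ValidationError("collinearity screen needs >= 2 traits and >= 3 individuals")
    full_corr = spearman_matrix(tm)
    dropped: list[str] = []
    current = list(tm.columns)

    while len(current) >= 2:
        corr = full_corr.loc[current, current].abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if not offends_mat(corr, threshold).any():
            break
        involved = sorted({current[i] for i in np.argwhere(offends_mat(corr, threshold)).ravel()})
        mean_r = {v: corr[current.index(v)].sum() / (len(current) - 1) for v in involved}
        victim = min(involved, key=lambda v: (-mean_r[v], v))
        dropped.append(victim)
        current.remove(victim)
    return tm[current], dropped, full_corr


def offends_mat(abs_corr: np.ndarray, threshold: float) -> np.ndarray:
    """Strict |r| > threshold; at exactly 1.0 the rule becomes >=, with a
    small tolerance because rank correlations of duplicated columns come
    back a few ulp below 1."""
    if threshold == 1.0:
        return abs_corr >= threshold - 1e-9
    return abs_corr > threshold
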