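"""Morphometric indices and regurgitate diet summaries.

SDI is the percent-difference size dimorphism index,
SDI = (1 - mean_male / mean_female) * 100, positive when females are the
larger sex (the reverse-dimorphism convention for sulids).  BCI is a body
condition index: PCA on standardized structural measurements (culmen,
tarsus, wing chord), then the residuals of an ordinary least squares
regression of body mass on PC1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["sdi", "bci", "diet_summary", "cv_percent", "cv_percent_from_moments"]

STRUCTURAL = ["culmen_mm", "tarsus_mm", "wing_mm"]


def sdi(mean_male: float, mean_female: float) -> float:
    """Percent-difference size dimorphism index.

    Positive values mean females exceed males; e.g. male 1274 g vs female
    1542 g gives 17.4%.
    """
    if mean_female <= 0:
        raise ValueError("mean_female must be > 0")
    return (1.0 - mean_male / mean_female) * 100.0


def bci(records: pd.DataFrame) -> pd.DataFrame:
    """Body condition index from mass-on-PC1 residuals.

    PCA is computed on the correlation matrix of the standardized
    structural variables (they carry different scales); PC1's sign is fixed
    so all loadings are positive (larger birds score higher).  Mass is the
    response in the OLS step, so BCI is mass unexplained by skeletal size;
    residuals sum to zero and are uncorrelated with PC1 by construction.
    Individuals with missing measurements are excluded with a warning.

    Returns a copy of the complete records with ``pc1`` and ``bci`` columns;
    PCA metadata (eigenvalue, percent variance explained, loadings) is
    attached in ``DataFrame.attrs``.
    """
    needed = STRUCTURAL + ["mass_g"]
    complete = records.dropna(subset=needed)
    if len(complete) < len(records):
        warnings.warn(f"excluded {len(records) - len(complete)} individuals with missing measurements")
    if len(complete) < 4:
        raise ValueError("need >= 4 complete individuals")
    Z = complete[STRUCTURAL].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    corr = Z.T @ Z / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    pc1_val = float(eigval[-1])
    loadings = eigvec[:, -1]
    if loadings.sum() < 0:
        loadings = -loadings
    pc1 = Z @ loadings
    mass = complete["mass_g"].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(pc1), pc1])
    beta, *_ = np.linalg.lstsq(design, mass, rcond=None)
    resid = mass - design @ beta
    out = complete.copy()
    out["pc1"] = pc1
    out["bci"] = resid
    out.attrs["pc1_eigenvalue"] = pc1_val
    out.attrs["pc1_var_share_pct"] = pc1_var_share_pct(pc1_val, len(STRUCTURAL))
    out.attrs["pc1_loadings"] = dict(zip(STRUCTURAL, loadings.tolist()))
    return out


def pc1_var_share_pct(eigenvalue: float, n_variables: int = 3) -> float:
    """Variance share of a principal component on standardized variables.

    On a correlation matrix of k variables total variance is k, so an
    eigenvalue e explains e / k * 100 percent.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    return eigenvalue / n_variables * 100.0


def diet_summary(items: pd.DataFrame, by: list[str] | None = None) -> dict:
    """Regurgitate diet aggregates.

    ``items`` is the long prey-item table (sample_id, species, length_mm,
    mass_g, plus grouping columns).  Per group (``by``, default none =
    everything pooled) returns:

    * ``fo_pct``: frequency of occurrence, the percent of samples
      containing each species;
    * ``mass_pct``: percent of pooled prey mass per species (sums to 100);
    * ``per_sample``: total mass (g), item count, and mean prey length (mm)
      per regurgitate — per-sample means are computed before any
      cross-sample statistic.
    """
    if items.empty:
        raise ValueError("need >= 1 sample")
    group_cols = list(by) if by else []

    def summarize(df: pd.DataFrame) -> dict:
        n_samples = df["sample_id"].nunique()
        fo = df.groupby("species")["sample_id"].nunique() / n_samples * 100.0
        mass = df.groupby("species")["mass_g"].sum()
        mass_pct = mass / mass.sum() * 100.0
        per_sample = df.groupby("sample_id").agg(
            total_mass_g=("mass_g", "sum"),
            n_items=("species", "size"),
            mean_length_mm=("length_mm", "mean"),
        )
        return {"fo_pct": fo, "mass_pct": mass_pct, "per_sample": per_sample, "n_samples": n_samples}

    if not group_cols:
        return summarize(items)
    return {key: summarize(grp) for key, grp in items.groupby(group_cols if len(group_cols) > 1 else group_cols[0])}


def cv_percent(values) -> float:
    """Coefficient of variation: sample SD / mean * 100."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(v.std(ddof=1) / mean * 100.0)


def cv_percent_from_moments(mean: float, sd: float) -> float:
    """CV from already-summarized mean and SD (e.g. printed group summaries)."""
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return sd / mean * 100.0
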