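"""Kinase-substrate enrichment analysis (KSEA) on phosphosite log2 fold changes.

Each kinase is scored by the standardized deviation of its substrates' mean
log2 fold change from the global mean over all quantified sites:

    z = (s_bar - p_bar) * sqrt(m) / delta

where ``s_bar`` is the mean log2 FC over the kinase's m mapped substrates,
``p_bar`` the mean over all sites, and ``delta`` the standard deviation of all
site log2 FCs (population SD by default, the KSEA App convention). Two-sided
normal p-values are Benjamini-Hochberg corrected across kinases.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Columns of a kinase-substrate map table.
MAP_COLUMNS = ("kinase", "substrate", "source", "networkin_score")


class DegenerateDataError(ValueError):
    """Raised when the site table cannot support a z-score (zero dispersion)."""


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    required = {"feature_id", "log2_fc"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    if "localization_confirmed" in sites.columns:
        sites = sites[sites["localization_confirmed"].astype(bool)]
    if not np.isfinite(sites["log2_fc"].to_numpy(float)).all():
        raise ValueError("site log2_fc values must be finite")
    return sites


def ksea_scores(
    sites: pd.DataFrame,
    ks_map: pd.DataFrame,
    networkin_cutoff: float = 0.0,
    substrate_cutoff: int = 0,
    ddof: int = 0,
) -> pd.DataFrame:
    """Score kinases from phosphosite log2 fold changes.

    Parameters
    ----------
    sites
        Phosphosite table with columns ``feature_id``, ``log2_fc`` and
        optionally ``localization_confirmed`` (only confirmed sites are used).
    ks_map
        Kinase-substrate map with columns ``kinase``, ``substrate``,
        ``source`` and ``networkin_score``. A (kinase, substrate) pair
        appearing under both sources counts once.
    networkin_cutoff
        Map rows with ``networkin_score`` below this are dropped (default 0,
        i.e. no filtering).
    substrate_cutoff
        Minimum substrate count; interpreted as no minimum beyond m >= 1 when
        0 (a kinase needs at least one mapped, quantified substrate).
    ddof
        Delta-degrees-of-freedom for the global SD delta (0 = population SD).

    Returns
    -------
    DataFrame with one row per retained kinase: kinase, m, s_bar, p_bar,
    delta, z, p_value, fdr; sorted by z descending.
    """
    sites = _check_sites(sites)
    if len(sites) < 2:
        raise DegenerateDataError("need >= 2 quantified sites")
    fc = sites.set_index("feature_id")["log2_fc"]
    fc = fc[~fc.index.duplicated(keep="first")]
    p_bar = float(fc.mean())
    delta = float(fc.std(ddof=ddof))
    if delta == 0:
        raise DegenerateDataError("site log2_fc dispersion is zero; z undefined")

    usable = ks_map[ks_map["networkin_score"] >= networkin_cutoff]
    usable = usable[usable["substrate"].isin(fc.index)]
    usable = usable.drop_duplicates(subset=["kinase", "substrate"])
    if usable.empty:
        warnings.warn("no usable kinase-substrate rows after filtering", stacklevel=2)
        return pd.DataFrame(columns=["kinase", "m", "s_bar", "p_bar", "delta", "z",
                                     "p_value", "fdr"])

    min_m = max(int(substrate_cutoff), 1)
    rows = []
    for kinase, grp in usable.groupby("kinase", sort=True):
        m = len(grp)
        if m < min_m:
            continue
        s_bar = float(fc.loc[grp["substrate"]].mean())
        z = (s_bar - p_bar) * np.sqrt(m) / delta
        rows.append({"kinase": kinase, "m": m, "s_bar": s_bar, "p_bar": p_bar,
                     "delta": delta, "z": z})
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no kinase passed the substrate-count cutoff", stacklevel=2)
        return pd.DataFrame(columns=["kinase", "m", "s_bar", "p_bar", "delta", "z",
                                     "p_value", "fdr"])
    out["p_value"] = 2 * stats.norm.sf(np.abs(out["z"]))
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("z", ascending=False).reset_index(drop=True)


def kinome_export(scores: pd.DataFrame) -> pd.DataFrame:
    """Kinome-tree annotation table (Coral input dialect).

    One row per kinase: branch value carries the FDR, node color the signed
    z-score and node size its absolute value; rows ordered by |z| descending.
    """
    if scores.empty:
        raise ValueError("scores table is empty")
    out = pd.DataFrame({
        "kinase": scores["kinase"],
        "branch_value": scores["fdr"],
        "node_color_value": scores["z"],
        "node_size_value": scores["z"].abs(),
    })
    return out.sort_values("node_size_value", ascending=False).reset_index(drop=True)


def sites_from_differential(records: pd.DataFrame,
                            site_labels: pd.Series | None = None) -> pd.DataFrame:
    """Build a KSEA site table from a phosphopeptide differential table."""
    sites = pd.DataFrame({
        "feature_id": records["feature_id"],
        "protein": records["gene_id"],
        "log2_fc": records["log2_ar"],
        "localization_confirmed": True,
    })
    if site_labels is not None:
        sites["site"] = site_labels.reindex(records["feature_id"]).values
    return sites
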