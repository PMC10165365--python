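"""Gene-set enrichment and directionality maps relative to the aging axis.

The set-level test follows the GAGE idea — a two-group mean statistic per
set — recast on the per-gene NB Wald z of a contrast: the set statistic is
the mean z over matched members, its null is the distribution of means of
random same-size gene draws (shared global permutations of the z vector),
and the two-sided p combines the two one-sided permutation tails.

The directionality map expresses, per pathway and contrast, whether member
genes move with or against the aging axis:

* concordance C in [-1, 1]: weighted mean of sign(LFC_contrast x LFC_AGE)
  with weights |LFC_AGE|, genes with zero age LFC excluded;
* magnitude ratio R >= 0: the set-level projection coefficient of the
  contrast's LFC vector onto the age LFC vector,
  |sum_g LFC_c(g) LFC_AGE(g)| / sum_g LFC_AGE(g)^2, so R = 1 when the
  contrast reproduces the age change exactly and R < 1 when its magnitude
  along the aging axis is reduced.

Calls per pathway: same_direction_as_aging when C(AGE_TREATED) > 0, and
reverted_toward_young when R(AGE_TREATED) < 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import GeneSetCollection, ParameterError


def gage_test(
    stats: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 10,
    seed: int = 0,
    stat_col: str = "z",
) -> pd.DataFrame:
    """Set-mean permutation test on per-gene statistics of one contrast.

    ``stats`` is a DE table with columns gene and ``stat_col``.  Returns one
    row per matched set: set, contrast, m, stat, pvalue (add-one permutation,
    two one-sided tails combined), qvalue (BH across sets within the contrast).
    Sets matching fewer than ``min_size`` genes are skipped.
    """
    z = stats[stat_col].to_numpy(dtype=float)
    contrast = stats["contrast"].iloc[0] if "contrast" in stats.columns and len(stats) else ""
    matched, _rate = sets.match(stats["gene"])
    sizes = {name: idx.size for name, idx in matched.items() if idx.size >= min_size}
    if not sizes:
        raise ParameterError(f"no gene set matched >= {min_size} genes")
    max_m = max(sizes.values())

    # Shared global permutations: prefix means of each permuted z give the
    # null mean for every set size at once.
    rng = np.random.default_rng(seed)
    prefix = np.empty((n_perm, max_m))
    for r in range(n_perm):
        perm = rng.permutation(z)[:max_m]
        prefix[r] = np.cumsum(perm) / np.arange(1, max_m + 1)

    rows = []
    for name, m in sizes.items():
        obs = float(z[matched[name]].mean())
        null = prefix[:, m - 1]
        p_up = (1 + int((null >= obs).sum())) / (n_perm + 1)
        p_dn = (1 + int((null <= obs).sum())) / (n_perm + 1)
        p = min(2.0 * min(p_up, p_dn), 1.0)
        rows.append({"set": name, "contrast": contrast, "m": m, "stat": obs, "pvalue": p})
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out


def directionality_map(
    de_tables: dict[str, pd.DataFrame],
    sets: GeneSetCollection,
    min_size: int = 10,
) -> pd.DataFrame:
    """Per (pathway, contrast) concordance C and magnitude ratio R vs the aging axis.

    ``de_tables`` maps the four contrast names to their DE tables and must
    include "AGE".  Calls (same_direction_as_aging, reverted_toward_young)
    are populated on the AGE_TREATED rows.
    """
    if "AGE" not in de_tables:
        raise ParameterError("directionality map requires the AGE contrast table")
    age = de_tables["AGE"].set_index("gene")["lfc"]
    rows = []
    for contrast, table in de_tables.items():
        lfc = table.set_index("gene")["lfc"]
        common = age.index.intersection(lfc.index)
        a_all, c_all = age.loc[common], lfc.loc[common]
        matched, _ = sets.match(pd.Series(common))
        for name, idx in matched.items():
            if idx.size < min_size:
                continue
            a = a_all.iloc[idx].to_numpy()
            c = c_all.iloc[idx].to_numpy()
            w = np.abs(a)
            nz = w > 0
            if not nz.any():
                continue
            C = float(np.sum(w[nz] * np.sign(c[nz] * a[nz])) / np.sum(w[nz]))
            R = float(np.abs(np.dot(c[nz], a[nz])) / np.dot(a[nz], a[nz]))
            rows.append(
                {"set": name, "contrast": contrast, "m": int(nz.sum()),
                 "concordance": C, "magnitude_ratio": R}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ParameterError("no gene set matched enough weighted members")
    out["same_direction_as_aging"] = pd.array([None] * len(out), dtype="boolean")
    out["reverted_toward_young"] = pd.array([None] * len(out), dtype="boolean")
    at = out["contrast"] == "AGE_TREATED"
    out.loc[at, "same_direction_as_aging"] = out.loc[at, "concordance"] > 0
    out.loc[at, "reverted_toward_young"] = out.loc[at, "magnitude_ratio"] < 1
    return out


def curate_pathways(
    results: pd.DataFrame,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
    q_threshold: float = 0.1,
) -> list[str]:
    """Declarative pathway curation: keep sets significant (q < threshold) in
    at least one contrast, intersected with an include list (empty list or
    None = keep all) minus an exclude list."""
    sig = results[results["qvalue"] < q_threshold]["set"].unique().tolist()
    if include:
        keep_lower = {s.lower() for s in include}
        sig = [s for s in sig if s.lower() in keep_lower]
    if exclude:
        drop_lower = {s.lower() for s in exclude}
        sig = [s for s in sig if s.lower() not in drop_lower]
    return sorted(sig)
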