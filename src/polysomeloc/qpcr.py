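"""ddCt qPCR analyses: drug-induced stability fold changes and polysome-pool
percentages with bacterial spike normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

POOLS = ("FM", "LP", "HP")


def stability_fold_change(records: pd.DataFrame) -> pd.DataFrame:
    """Drug-normalized stability ratio per biological replicate for one gene.

    ``records`` holds one gene's Ct table with columns treatment, bio_rep,
    tech_rep, timepoint (``0h``/``6h``), ct_target, ct_reference. Technical
    replicates are averaged first. Per replicate and treatment:
    dCt = Ct_target - Ct_reference; ddCt = dCt(6h) - dCt(0h);
    FC = 2^(-ddCt). The reported value is FC_treated / FC_control per
    biological replicate and treatment. Replicates missing a timepoint are
    skipped.

    Returns a DataFrame: treatment, bio_rep, fold_change_treated,
    fold_change_control, ratio.
    """
    tech_mean = (
        records.groupby(["treatment", "bio_rep", "timepoint"], as_index=False)[
            ["ct_target", "ct_reference"]
        ].mean()
    )
    tech_mean["dct"] = tech_mean["ct_target"] - tech_mean["ct_reference"]
    wide = tech_mean.pivot_table(
        index=["treatment", "bio_rep"], columns="timepoint", values="dct"
    )
    rows = []
    treatments = [t for t in wide.index.get_level_values("treatment").unique() if t != "control"]
    for treatment in treatments:
        for bio in wide.loc[treatment].index:
            try:
                ddct_t = wide.loc[(treatment, bio), "6h"] - wide.loc[(treatment, bio), "0h"]
                ddct_c = wide.loc[("control", bio), "6h"] - wide.loc[("control", bio), "0h"]
            except KeyError:
                continue
            if pd.isna(ddct_t) or pd.isna(ddct_c):
                continue
            fc_t = 2.0 ** (-ddct_t)
            fc_c = 2.0 ** (-ddct_c)
            rows.append(
                {
                    "treatment": treatment,
                    "bio_rep": bio,
                    "fold_change_treated": fc_t,
                    "fold_change_control": fc_c,
                    "ratio": fc_t / fc_c,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["treatment", "bio_rep", "fold_change_treated", "fold_change_control", "ratio"],
    )


def stability_test(ratios: np.ndarray) -> float:
    """One-sided one-sample t-test of stabilization: H1 mean log2(ratio) > 0.

    Fold-change ratios are ratio-distributed, so the test runs on the log2
    scale. Requires >=2 replicates.
    """
    values = np.asarray(ratios, dtype=float)
    if values.size < 2:
        raise ValueError("need >=2 replicate ratios for the t-test")
    logs = np.log2(values)
    if logs.std(ddof=1) == 0.0:
        # Zero spread: t is 0 at the null boundary, +/-inf otherwise.
        mean = logs.mean()
        return 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
    result = stats.ttest_1samp(logs, 0.0, alternative="greater")
    return float(result.pvalue)


def stability_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-treatment stability summary over a full Ct table:
    mean ratio across biological replicates and the one-sided p-value."""
    rows = []
    for gene, records in ct_table.groupby("gene"):
        fc = stability_fold_change(records)
        for treatment, sub in fc.groupby("treatment"):
            ratios = sub["ratio"].to_numpy()
            rows.append(
                {
                    "gene": gene,
                    "treatment": treatment,
                    "n_replicates": len(ratios),
                    "mean_ratio": float(ratios.mean()),
                    "p_value": stability_test(ratios) if len(ratios) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pool_percentages(records: pd.DataFrame) -> pd.Series:
    """Percentage of one transcript's RNA in each of the FM/LP/HP pools.

    amount_p = 2^-(Ct_target - mean(Ct_dap, Ct_thr)): the spike mean anchors
    each pool's scale (spikes were added at equal amounts per pool). The
    three percentages sum to 100.
    """
    indexed = records.set_index("pool")
    missing = set(POOLS) - set(indexed.index)
    if missing:
        raise ValueError(f"missing pools: {sorted(missing)}")
    amounts = {}
    for pool in POOLS:
        row = indexed.loc[pool]
        spike = 0.5 * (row["ct_spike_dap"] + row["ct_spike_thr"])
        amounts[pool] = 2.0 ** (-(row["ct_target"] - spike))
    total = sum(amounts.values())
    return pd.Series({pool: 100.0 * amounts[pool] / total for pool in POOLS})


def pool_percentage_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Pool percentages for every transcript in a qPCR Ct table."""
    rows = []
    for tid, records in ct_table.groupby("transcript_id"):
        pct = pool_percentages(records)
        rows.append({"transcript_id": tid, **pct.to_dict()})
    return pd.DataFrame(rows, columns=["transcript_id", *POOLS])


def concordance(qpcr_pct: np.ndarray, array_pct: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired qPCR and array
    pool percentages over transcripts x pools."""
    a = np.asarray(qpcr_pct, dtype=float)
    b = np.asarray(array_pct, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if a.size < 3:
        raise ValueError("need >=3 pairs for a correlation")
    result = stats.pearsonr(a, b)
    return float(result.statistic), float(result.pvalue)
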