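"""Substitution/polymorphism excess validation of positive-selection calls.

Adaptive fixation inflates fixed inter-species differences relative to
segregating intra-species variants, so enhancers called under positive
selection should show a higher substitutions-to-polymorphisms ratio than
the rest.  Counts are pooled into one 2x2 table (positive/nonpositive x
substitutions/polymorphisms) and compared with a two-sided Fisher exact
test; per-group ratios are reported for diagnostics.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .conservation import fisher_exact

__all__ = ["build_records", "tabulate", "excess_test", "mk_summary"]


def build_records(
    selection_results: pd.DataFrame, snp_table: pd.DataFrame
) -> pd.DataFrame:
    """Join selection-test results with per-enhancer SNP counts.

    SNPs are counted within the enhancer irrespective of which alignment
    columns entered the selection test.  Enhancers missing from the SNP
    table are dropped.
    """
    if not {"enhancer_id", "n_snps"}.issubset(snp_table.columns):
        raise ValueError("snp_table needs columns enhancer_id and n_snps")
    merged = selection_results.merge(snp_table, on="enhancer_id", how="inner")
    return merged.rename(columns={"n_snps": "n_polymorphisms"})[
        ["enhancer_id", "n_substitutions", "n_polymorphisms", "positive_call"]
    ]


def tabulate(records: pd.DataFrame) -> dict:
    """Pooled 2x2 counts and per-group substitution/polymorphism ratios.

    Rows of the table are (positive, nonpositive); columns are
    (substitutions, polymorphisms).  A group ratio is ``nan`` when the
    group has zero polymorphisms.
    """
    required = {"n_substitutions", "n_polymorphisms", "positive_call"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if (records["n_substitutions"] < 0).any() or (records["n_polymorphisms"] < 0).any():
        raise ValueError("counts must be nonnegative")
    pos = records[records["positive_call"]]
    non = records[~records["positive_call"]]
    if len(pos) == 0 or len(non) == 0:
        raise ValueError("both positive and nonpositive groups must be non-empty")
    table = np.array(
        [
            [int(pos["n_substitutions"].sum()), int(pos["n_polymorphisms"].sum())],
            [int(non["n_substitutions"].sum()), int(non["n_polymorphisms"].sum())],
        ]
    )

    def ratio(subs: int, poly: int) -> float:
        return subs / poly if poly > 0 else np.nan

    return {
        "table": table,
        "ratio_positive": ratio(table[0, 0], table[0, 1]),
        "ratio_nonpositive": ratio(table[1, 0], table[1, 1]),
        "n_positive": len(pos),
        "n_nonpositive": len(non),
    }


def excess_test(table: np.ndarray) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the pooled 2x2 table."""
    return fisher_exact(table)


def mk_summary(
    selection_results: pd.DataFrame,
    snp_table: pd.DataFrame,
    label: Optional[str] = None,
) -> pd.DataFrame:
    """One-row summary: pooled counts, ratios, odds ratio and Fisher p."""
    records = build_records(selection_results, snp_table)
    tab = tabulate(records)
    odds, p = excess_test(tab["table"])
    return pd.DataFrame(
        [
            {
                **({"stage": label} if label is not None else {}),
                "n_positive_enhancers": tab["n_positive"],
                "n_nonpositive_enhancers": tab["n_nonpositive"],
                "subs_positive": tab["table"][0, 0],
                "poly_positive": tab["table"][0, 1],
                "subs_nonpositive": tab["table"][1, 0],
                "poly_nonpositive": tab["table"][1, 1],
                "ratio_positive": tab["ratio_positive"],
                "ratio_nonpositive": tab["ratio_nonpositive"],
                "odds_ratio": odds,
                "fisher_p": p,
            }
        ]
    )
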