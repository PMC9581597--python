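"""Group comparisons and reporting for per-patient measurements.

Three-group designs (non-tumor skin, metastatic, disease-free) are tested
by one-way ANOVA followed by Tukey's HSD for all pairwise comparisons
(Bonferroni-adjusted t-tests available as an option); two-group designs by
Student's t-test (equal-variance by default, Welch optional).  Significance
stars follow the conventional strict thresholds: * p < 0.05, ** p < 0.01,
*** p < 0.001, **** p < 0.0001.  The unit of analysis is the patient:
average a patient's fields before comparing groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star tier for a p-value (strict inequalities; '' = not significant)."""
    if not np.isfinite(p):
        raise ValueError(f"non-finite p-value: {p}")
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return ""


@dataclass
class GroupComparison:
    """Result of one measurement's group comparison."""

    measurement: str
    design: str
    test: str
    groups: dict[str, np.ndarray]
    statistic: float
    pvalue: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.pvalue)

    @property
    def pairwise_stars(self) -> dict[tuple[str, str], str]:
        return {pair: significance_stars(p) for pair, p in self.pairwise.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "measurement": self.measurement,
                "comparison": "overall",
                "test": self.test,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "stars": self.stars,
            }
        ]
        for (a, b), p in self.pairwise.items():
            rows.append(
                {
                    "measurement": self.measurement,
                    "comparison": f"{a} vs {b}",
                    "test": "tukey_hsd" if self.test == "anova" else self.test,
                    "statistic": np.nan,
                    "pvalue": p,
                    "stars": significance_stars(p),
                }
            )
        return pd.DataFrame(rows)


def compare_groups(
    groups: dict[str, np.ndarray],
    design: str = "three_group",
    *,
    measurement: str = "",
    posthoc: str = "tukey",
    equal_var: bool = True,
) -> GroupComparison:
    """Compare per-sample values across groups.

    ``three_group`` (any >= 2 groups, in fact): one-way ANOVA for the
    overall effect, then all pairwise comparisons with familywise
    adjustment — Tukey HSD by default, Bonferroni-adjusted t-tests with
    ``posthoc='bonferroni'``.  ``two_group``: two-sided Student's t-test
    (``equal_var=False`` for Welch).
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} values; need >= 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        clean[name] = arr

    names = list(clean)
    if design == "two_group":
        if len(names) != 2:
            raise ValueError(f"two_group design needs exactly 2 groups, got {len(names)}")
        res = sps.ttest_ind(clean[names[0]], clean[names[1]], equal_var=equal_var)
        return GroupComparison(
            measurement=measurement,
            design=design,
            test="student_t" if equal_var else "welch_t",
            groups=clean,
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
        )
    if design != "three_group":
        raise ValueError(f"unknown design {design!r}")
    if len(names) < 2:
        raise ValueError("need at least 2 groups")

    f_stat, f_p = sps.f_oneway(*clean.values())
    pairwise: dict[tuple[str, str], float] = {}
    if posthoc == "tukey":
        res = sps.tukey_hsd(*clean.values())
        for i, j in itertools.combinations(range(len(names)), 2):
            pairwise[(names[i], names[j])] = float(res.pvalue[i, j])
    elif posthoc == "bonferroni":
        pairs = list(itertools.combinations(names, 2))
        for a, b in pairs:
            p = float(sps.ttest_ind(clean[a], clean[b], equal_var=True).pvalue)
            pairwise[(a, b)] = min(1.0, p * len(pairs))
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return GroupComparison(
        measurement=measurement,
        design=design,
        test="anova",
        groups=clean,
        statistic=float(f_stat),
        pvalue=float(f_p),
        pairwise=pairwise,
    )


def build_report(
    comparisons: list[GroupComparison],
    tables: dict[str, pd.DataFrame] | None = None,
    out_dir: str | Path = "report",
    *,
    make_plots: bool = False,
) -> dict[str, Path]:
    """Write statistics tables (and optional box plots) to ``out_dir``.

    Returns the paths written.  Plots use the non-interactive Agg backend.
    """
    if not comparisons and not tables:
        raise ValueError("nothing to report: no comparisons or tables")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if comparisons:
        stats_df = pd.concat([c.to_frame() for c in comparisons], ignore_index=True)
        path = out_dir / "statistics.csv"
        stats_df.to_csv(path, index=False)
        written["statistics"] = path
        summary = "\n".join(
            f"{c.measurement or '(unnamed)'} [{c.test}]: stat={c.statistic:.4g}, "
            f"p={c.pvalue:.4g} {c.stars or 'ns'}"
            for c in comparisons
        )
        spath = out_dir / "summary.txt"
        spath.write_text(summary + "\n")
        written["summary"] = spath

    for name, table in (tables or {}).items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        written[name] = path

    if make_plots and comparisons:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for c in comparisons:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.boxplot(list(c.groups.values()), tick_labels=list(c.groups))
            ax.set_title(f"{c.measurement} (p={c.pvalue:.3g} {c.stars})")
            ax.set_ylabel(c.measurement)
            fig.tight_layout()
            path = out_dir / f"{(c.measurement or 'comparison').replace('/', '_')}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written[f"plot:{c.measurement}"] = path
    return written
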