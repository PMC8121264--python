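"""End-to-end analysis: read -> filter -> collapse -> endpoints -> inference.

The stages run in a fixed order: inclusion criteria, positional
collapse, endpoint computation, per-cell Grubbs screening, then the
traditional litter-mean comparison and the layered positional ANOVAs.
All intermediate tables are kept on the report object so every number
in the final summary is traceable, and can be written out as tidy CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import endpoints as ep
from .inference import PositionalAnalyses, TTestResult, cohens_d, run_positional_analyses, students_t_test
from .positions import collapse_dataset
from .qc import MIN_LITTER, ExclusionReport, apply_inclusion_criteria, grubbs_single_pass
from .records import StudyDataset


def litter_rule_dataset(dataset: StudyDataset) -> StudyDataset:
    """Dams with litters of at least five feti, all horns retained.

    The traditional litter-mean comparison applies only the litter rule,
    so small horns still contribute their feti there.
    """
    dams = [d for d in dataset.dams if d.litter_size >= MIN_LITTER]
    control = dataset.control_label
    if dams and control not in {d.group_label for d in dams}:
        control = dams[0].group_label
    return StudyDataset(dams=dams, control_label=control)


def screen_endpoint_table(
    endpoint_df: pd.DataFrame,
    alpha: float = 0.05,
    report: Optional[ExclusionReport] = None,
) -> pd.DataFrame:
    """Grubbs-screen an endpoint table within each analysis cell.

    A cell is one (endpoint, group, horn side, position) combination;
    screening one cell can therefore never mix treatment effects with
    outliers. Removed values are appended to ``report.outliers_removed``
    when a report is given.
    """
    drop: list = []
    for (endpoint, group, side, pos), cell in endpoint_df.groupby(
        ["endpoint", "group_label", "horn_side", "position"], sort=False
    ):
        pairs = list(zip(cell.index.tolist(), cell["value"].tolist()))
        while len(pairs) >= 3:
            res = grubbs_single_pass([v for _, v in pairs], alpha=alpha)
            if res.outlier_index is None:
                break
            idx, value = pairs.pop(res.outlier_index)
            drop.append(idx)
            if report is not None:
                report.outliers_removed.append((group, side, pos, endpoint, float(value)))
    return endpoint_df.drop(index=drop)


@dataclass
class RunReport:
    """Everything one analysis run produced, ready to export."""

    control_label: str
    alpha: float
    exclusions: ExclusionReport
    traditional: pd.DataFrame
    traditional_tests: dict[str, TTestResult]
    traditional_effect_sizes: dict[str, float]
    endpoint_table: pd.DataFrame
    cell_summary: pd.DataFrame
    positional: dict[str, PositionalAnalyses] = field(default_factory=dict)

    def contrast_frame(self) -> pd.DataFrame:
        """All Sidak contrasts as one tidy frame (one row per contrast)."""
        rows = []
        for endpoint, analyses in self.positional.items():
            for group, res in analyses.within_group.items():
                for c in res.pairwise:
                    rows.append(
                        dict(endpoint=endpoint, layer="within_group", group=group,
                             horn_side="R-vs-L", position=c.within_level,
                             mean_diff=c.mean_diff, t=c.t_statistic,
                             raw_p=c.raw_p, sidak_p=c.sidak_p,
                             significant=c.significant)
                    )
            for (group, side), res in analyses.vs_control.items():
                for c in res.pairwise:
                    rows.append(
                        dict(endpoint=endpoint, layer="vs_control", group=group,
                             horn_side=side, position=c.within_level,
                             mean_diff=c.mean_diff, t=c.t_statistic,
                             raw_p=c.raw_p, sidak_p=c.sidak_p,
                             significant=c.significant)
                    )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = []
        lines.extend(self.exclusions.summary_lines())
        lines.append("")
        lines.append("Traditional analysis (dam means, raw fetal weight, g):")
        for _, row in self.traditional.iterrows():
            star = ""
            t = self.traditional_tests.get(row["group_label"])
            if t is not None and t.p_value < self.alpha:
                star = " *"
            pct = row["percent_decrease"]
            pct_txt = f", decrease {int(pct)}%" if pd.notna(pct) else ""
            lines.append(
                f"  {row['group_label']}: {row['fetal_weight_mean_g']:.2f} "
                f"± {row['fetal_weight_sem_g']:.2f} (n={int(row['n_dams'])}"
                f"{pct_txt}){star}"
            )
        contrasts = self.contrast_frame()
        if len(contrasts):
            sig = contrasts[contrasts["significant"]]
            lines.append("")
            lines.append(
                f"Positional contrasts: {len(sig)} significant of {len(contrasts)} "
                f"(Sidak p < {self.alpha}):"
            )
            for _, c in sig.iterrows():
                lines.append(
                    f"  * {c['endpoint']} [{c['layer']}] {c['group']} "
                    f"{c['horn_side']} {c['position']}: diff={c['mean_diff']:.4g}, "
                    f"Sidak p={c['sidak_p']:.4g}"
                )
        return "\n".join(lines)

    def write(self, outdir: Union[str, Path]) -> None:
        """Export every table (tidy CSVs) plus the human-readable summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([g.as_row() for g in self.exclusions.groups.values()]).to_csv(
            outdir / "exclusions.csv", index=False
        )
        pd.DataFrame(
            self.exclusions.outliers_removed,
            columns=["group_label", "horn_side", "position", "endpoint", "value"],
        ).to_csv(outdir / "outliers_removed.csv", index=False)
        self.traditional.to_csv(outdir / "traditional_summary.csv", index=False)
        self.endpoint_table.to_csv(outdir / "endpoint_table.csv", index=False)
        self.cell_summary.to_csv(outdir / "cell_summary.csv", index=False)
        self.contrast_frame().to_csv(outdir / "contrasts.csv", index=False)
        anova_rows = []
        for endpoint, analyses in self.positional.items():
            layers = [("within_group", analyses.within_group.items())] + [
                ("vs_control", analyses.vs_control.items())
            ]
            for layer, items in layers:
                for key, res in items:
                    label = key if isinstance(key, str) else "|".join(key)
                    for source, row in res.table.items():
                        anova_rows.append(
                            dict(endpoint=endpoint, layer=layer, unit=label,
                                 source=source, **row)
                        )
        pd.DataFrame(anova_rows).to_csv(outdir / "anova_tables.csv", index=False)
        (outdir / "report.txt").write_text(self.summary_text() + "\n")


def analyze_dataset(
    dataset: StudyDataset,
    alpha: float = 0.05,
    endpoints: tuple[str, ...] = ep.ENDPOINTS,
) -> RunReport:
    """Run the complete analysis on an in-memory dataset."""
    filtered, exclusions = apply_inclusion_criteria(dataset)

    # traditional layer: litter rule only — every fetus of every dam with a
    # litter of at least five contributes, small horns included
    trad_ds = litter_rule_dataset(dataset)
    traditional = ep.traditional_table(trad_ds)
    trad_tests: dict[str, TTestResult] = {}
    trad_d: dict[str, float] = {}
    _, dam_means = ep.traditional_summary(trad_ds)
    control_means = [
        dam_means[d.dam_id] for d in trad_ds.dams_in_group(trad_ds.control_label)
    ]
    for label in trad_ds.exposed_labels():
        means = [dam_means[d.dam_id] for d in trad_ds.dams_in_group(label)]
        if len(means) >= 2 and len(control_means) >= 2:
            trad_tests[label] = students_t_test(
                means, control_means, label, trad_ds.control_label
            )
            trad_d[label] = cohens_d(
                means, control_means, f"{label} vs {trad_ds.control_label} (dam means)"
            ).cohens_d

    observations = collapse_dataset(filtered)
    endpoint_table = ep.compute_endpoint_table(observations, endpoints)
    endpoint_table = screen_endpoint_table(endpoint_table, alpha=alpha, report=exclusions)
    cell_summary = (
        ep.positional_cell_summary(endpoint_table) if len(endpoint_table) else pd.DataFrame()
    )

    positional: dict[str, PositionalAnalyses] = {}
    for endpoint in endpoints:
        sub = endpoint_table[endpoint_table["endpoint"] == endpoint]
        if sub["group_label"].nunique() >= 1 and len(sub):
            try:
                positional[endpoint] = run_positional_analyses(
                    sub, filtered.control_label, alpha=alpha
                )
            except ValueError:
                pass

    return RunReport(
        control_label=filtered.control_label,
        alpha=alpha,
        exclusions=exclusions,
        traditional=traditional,
        traditional_tests=trad_tests,
        traditional_effect_sizes=trad_d,
        endpoint_table=endpoint_table,
        cell_summary=cell_summary,
        positional=positional,
    )
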