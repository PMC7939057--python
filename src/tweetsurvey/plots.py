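"""Figure export: forest plots of odds ratios and bar charts of attention
ratios and sentiment polarities per stratum."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

logger = logging.getLogger(__name__)


def _forest(ax, sub: pd.DataFrame, title: str) -> None:
    sub = sub.dropna(subset=["or"])
    y = range(len(sub))
    ors = sub["or"].to_numpy(dtype=float)
    ax.errorbar(
        ors, list(y),
        xerr=[ors - sub["ci_low"].to_numpy(dtype=float),
              sub["ci_high"].to_numpy(dtype=float) - ors],
        fmt="o", capsize=3, color="tab:blue",
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(sub["conditions"])
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_title(title)
    ax.invert_yaxis()


def export_figures(
    suite: pd.DataFrame,
    out_dir: str | Path,
    emotion_results: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the standard figure set; returns the created paths.

    Empty inputs produce a warning and no files.
    """
    out_dir = Path(out_dir)
    if suite is None or suite.empty:
        logger.warning("export_figures: no result tables, nothing to plot")
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    uni = suite[suite["analysis"] == "univariate"]
    if not uni.empty:
        panels = [
            ("user_type", uni[uni["conditions"].str.startswith("user_type")]),
            ("gender", uni[uni["conditions"].str.startswith("gender")]),
            ("age group", uni[uni["conditions"].str.startswith("age_group")]),
            ("concern", uni[uni["conditions"].str.startswith("concern")]),
        ]
        fig, axes = plt.subplots(2, 2, figsize=(11, 7))
        for ax, (title, sub) in zip(axes.ravel(), panels):
            _forest(ax, sub, title)
        fig.suptitle("Univariate COVID-attention odds ratios")
        fig.tight_layout()
        path = out_dir / "univariate_forest.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        created.append(path)

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(12, 4.5))
        ax1.barh(uni["conditions"], uni["ratio"], color="tab:orange")
        ax1.set_xlabel("attention ratio (%)")
        ax1.set_title("COVID attention by group")
        ax1.invert_yaxis()
        sent = uni.dropna(subset=["mean_polarity"])
        ax2.barh(sent["conditions"], sent["mean_polarity"], color="tab:green")
        ax2.set_xlabel("mean sentiment polarity (COVID subset)")
        ax2.set_title("Sentiment by group")
        ax2.invert_yaxis()
        fig.tight_layout()
        path = out_dir / "univariate_ratios_sentiment.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        created.append(path)

    tri = suite[(suite["analysis"] == "trivariate")]
    if not tri.empty and tri["or"].notna().any():
        fig, ax = plt.subplots(figsize=(8, 0.28 * len(tri) + 1.5))
        _forest(ax, tri, "Trivariate (gender x age x concern) odds ratios")
        fig.tight_layout()
        path = out_dir / "trivariate_forest.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        created.append(path)

    if emotion_results is not None and not emotion_results.empty:
        emo = emotion_results.dropna(subset=["or"])
        if not emo.empty:
            fig, ax = plt.subplots(figsize=(8, 0.32 * len(emo) + 1.5))
            labels = emo["conditions"] + " / " + emo["emotion"]
            y = range(len(emo))
            ors = emo["or"].to_numpy(dtype=float)
            ax.errorbar(
                ors, list(y),
                xerr=[ors - emo["ci_low"].to_numpy(dtype=float),
                      emo["ci_high"].to_numpy(dtype=float) - ors],
                fmt="s", capsize=3, color="tab:red",
            )
            ax.axvline(1.0, color="grey", lw=0.8, ls="--")
            ax.set_yticks(list(y))
            ax.set_yticklabels(labels)
            ax.set_xlabel("odds ratio (95% CI)")
            ax.set_title("Dominant-emotion odds ratios (COVID subset)")
            ax.invert_yaxis()
            fig.tight_layout()
            path = out_dir / "emotion_or_forest.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            created.append(path)

    return created
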