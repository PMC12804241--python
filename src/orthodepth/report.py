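"""Per-lexicon depth reports and cross-language comparison.

:func:`compute_all` runs the entire measure battery on one lexicon and
collects the results in a :class:`DepthReport`; failures of individual
measures are downgraded to skipped-with-reason so one bad input never
voids a whole report.  :func:`correlate_and_project` compares several
reports: Pearson correlations between measures across languages and a PCA
on the standardized measure matrix, the analysis that separates the
unpredictability-family measures from the complexity-family ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import LanguageConfig
from .distance import OPCResult, mean_opc
from .errors import MeasureError, NoParseError, OrthodepthError
from .information import EfficiencyProfile, efficiency_profile_all
from .lexicon import Lexicon, filter_monosyllabic
from .rule_measures import (
    BasicSummary,
    RuleSystemSummary,
    basic_summary,
    classify_rules,
    irregularity_detail,
)
from .rules import GPCRule
from .segmentation import parse_graphemes, parse_syllable
from .statistical import ConsistencyScores, EntropySummary, entropy_summary, unit_consistency

log = logging.getLogger(__name__)

__all__ = [
    "DepthReport",
    "CrossLanguageSummary",
    "compute_all",
    "correlate_and_project",
    "item_table",
    "DEFAULT_MEASURES",
]

#: Measure columns entering the cross-language matrix by default.
DEFAULT_MEASURES = (
    "n_unique_gp_mappings",
    "pct_equal_length",
    "n_single",
    "n_multi",
    "n_context",
    "pct_irregular",
    "vowel_consistency",
    "body_consistency",
    "entropy_ci",
    "entropy_onset_cond",
    "entropy_coda_cond",
    "efficiency_letters",
    "efficiency_graphemes",
    "mean_opc",
    "onset_entropy",
)


@dataclass(frozen=True)
class DepthReport:
    """All measure values for one lexicon (one row of a cross-language table)."""

    language_tag: str
    n_words_total: int
    n_words: int  # monosyllabic entries the measures ran on
    basic: Optional[BasicSummary] = None
    rules: Optional[RuleSystemSummary] = None
    vowel_consistency: Optional[ConsistencyScores] = None
    body_consistency: Optional[ConsistencyScores] = None
    entropy: Optional[EntropySummary] = None
    efficiency: dict[str, EfficiencyProfile] = field(default_factory=dict)
    opc: Optional[OPCResult] = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # ------------------------------------------------------------- flat view
    def measure_vector(self) -> dict[str, Optional[float]]:
        """Flat named map of the scalar measures (None where skipped)."""
        v: dict[str, Optional[float]] = dict.fromkeys(DEFAULT_MEASURES)
        if self.basic is not None:
            v["pct_equal_length"] = self.basic.pct_equal_length
            v["n_unique_gp_mappings"] = self.basic.n_unique_gp_mappings
        if self.rules is not None:
            v["n_single"] = self.rules.n_single
            v["n_multi"] = self.rules.n_multi
            v["n_context"] = self.rules.n_context
            v["pct_irregular"] = self.rules.pct_irregular
        if self.vowel_consistency is not None:
            v["vowel_consistency"] = self.vowel_consistency.mean
        if self.body_consistency is not None:
            v["body_consistency"] = self.body_consistency.mean
        if self.entropy is not None:
            v["onset_entropy"] = self.entropy.onset_entropy
            v["entropy_ci"] = self.entropy.vowel_entropy_ci
            v["entropy_onset_cond"] = self.entropy.vowel_entropy_onset_cond
            v["entropy_coda_cond"] = self.entropy.vowel_entropy_coda_cond
        for level, prof in self.efficiency.items():
            if f"efficiency_{level}" in v:
                v[f"efficiency_{level}"] = prof.efficiency
        if self.opc is not None:
            v["mean_opc"] = self.opc.mean_opc
        return v

    # ---------------------------------------------------------------- json
    def to_dict(self) -> dict:
        def _eff(p: EfficiencyProfile) -> dict:
            return {
                "h_p": p.h_p,
                "h_p_given_o": p.h_p_given_o,
                "mi": p.mi,
                "efficiency": p.efficiency,
                "n_observations": p.n_observations,
            }

        d: dict = {
            "language_tag": self.language_tag,
            "n_words_total": self.n_words_total,
            "n_words": self.n_words,
            "skipped": dict(sorted(self.skipped.items())),
            "provenance": self.provenance,
        }
        if self.basic is not None:
            d["basic"] = {
                "n_letters": self.basic.n_letters,
                "n_graphemes": self.basic.n_graphemes,
                "n_phonemes": self.basic.n_phonemes,
                "pct_equal_length": self.basic.pct_equal_length,
                "n_unique_gp_mappings": self.basic.n_unique_gp_mappings,
            }
        if self.rules is not None:
            d["rules"] = {
                "n_single": self.rules.n_single,
                "n_multi": self.rules.n_multi,
                "n_context": self.rules.n_context,
                "pct_each": self.rules.pct_each,
                "pct_irregular": self.rules.pct_irregular,
                "n_no_rule": self.rules.n_no_rule,
            }
        if self.vowel_consistency is not None:
            d["consistency"] = {
                "vowel": self.vowel_consistency.mean,
                "body": self.body_consistency.mean if self.body_consistency else None,
            }
        if self.entropy is not None:
            d["entropy"] = {
                "onset_entropy": self.entropy.onset_entropy,
                "context_independent": self.entropy.vowel_entropy_ci,
                "onset_conditional": self.entropy.vowel_entropy_onset_cond,
                "coda_conditional": self.entropy.vowel_entropy_coda_cond,
            }
        if self.efficiency:
            d["efficiency"] = {lvl: _eff(p) for lvl, p in sorted(self.efficiency.items())}
        if self.opc is not None:
            d["opc"] = {
                "mean_opc": self.opc.mean_opc,
                "n_sampled": self.opc.n_sampled,
                "n_excluded": self.opc.n_excluded,
                "seed": self.opc.seed,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=False, indent=1)


def _hash_config(config: LanguageConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def _hash_rules(rules: Sequence[GPCRule]) -> str:
    blob = "\n".join(
        f"{r.grapheme}|{' '.join(r.phonemes)}|{r.position}|{r.pre_context}|{r.post_context}"
        for r in rules
    )
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def compute_all(
    lexicon: Lexicon,
    rules: Optional[Sequence[GPCRule]] = None,
    *,
    seed: int = 0,
    sample_size: int = 1000,
    weighted: bool = False,
    windows: str = "overlapping",
) -> DepthReport:
    """Run every measure on a lexicon and assemble the report.

    The lexicon is first restricted to monosyllables (all measures here are
    defined on them).  Rule-based and grapheme-grain measures are skipped
    with a reason when no rule table is supplied; any measure that raises is
    likewise downgraded to a skip.
    """
    n_total = len(lexicon)
    mono = filter_monosyllabic(lexicon)
    skipped: dict[str, str] = {}

    syllabic = []
    n_unsyllabifiable = 0
    for e in mono:
        try:
            parse_syllable(e, mono.config)
            syllabic.append(e)
        except MeasureError:
            n_unsyllabifiable += 1
    if n_unsyllabifiable:
        log.warning("%d monosyllables lack a vowel letter or nucleus; dropped", n_unsyllabifiable)
    work = replace(mono, entries=tuple(syllabic))

    report = DepthReport(
        language_tag=lexicon.language_tag,
        n_words_total=n_total,
        n_words=len(work),
        skipped=skipped,
        provenance={
            "toolkit_version": __version__,
            "config_hash": _hash_config(lexicon.config),
            "rules_hash": _hash_rules(rules) if rules else None,
            "seed": seed,
            "sample_size": sample_size,
            "weighted": weighted,
            "windows": windows,
            "n_dropped_polysyllabic": n_total - len(mono),
            "n_dropped_unsyllabifiable": n_unsyllabifiable,
        },
    )
    if len(work) == 0:
        skipped["all"] = "no monosyllabic entries"
        return report

    parses = None
    if rules:
        parses = []
        n_unparsed = 0
        for e in work:
            try:
                parses.append(parse_graphemes(e, rules, allow_mismatch=True))
            except NoParseError:
                n_unparsed += 1
        report.provenance["n_unparsed_graphemes"] = n_unparsed

    def attempt(name, fn):
        try:
            return fn()
        except (OrthodepthError, ValueError) as e:
            log.warning("measure %s skipped: %s", name, e)
            skipped[name] = str(e)
            return None

    basic = attempt("basic", lambda: basic_summary(work, parses))
    rules_summary = None
    if rules:
        rules_summary = attempt("rules", lambda: classify_rules(rules))
        if rules_summary is not None:
            detail = attempt("pct_irregular", lambda: irregularity_detail(work, rules))
            if detail is not None:
                rules_summary = replace(
                    rules_summary, pct_irregular=detail[0], n_no_rule=detail[2]
                )
    else:
        skipped["rules"] = "no GPC rule table supplied"

    vowel_c = attempt("vowel_consistency", lambda: unit_consistency(work, "vowel", weighted=weighted))
    body_c = attempt("body_consistency", lambda: unit_consistency(work, "body", weighted=weighted))
    ent = attempt("entropy", lambda: entropy_summary(work, weighted=weighted))
    eff = attempt(
        "efficiency",
        lambda: efficiency_profile_all(work, rules, windows=windows),
    )
    if eff is not None and rules is None:
        skipped["efficiency_graphemes"] = "no GPC rule table supplied"
    opc = attempt("opc", lambda: mean_opc(work, sample_size=sample_size, seed=seed))

    return replace(
        report,
        basic=basic,
        rules=rules_summary,
        vowel_consistency=vowel_c,
        body_consistency=body_c,
        entropy=ent,
        efficiency=eff or {},
        opc=opc,
    )


def item_table(
    lexicon: Lexicon,
    *,
    seed: int = 0,
    sample_size: int = 1000,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-word measure table for item-level research use.

    One row per monosyllabic entry: orthography, phonology, vowel and body
    consistency, and OPC (NaN for words outside the OPC sample or without
    orthographic neighbors).
    """
    work = filter_monosyllabic(lexicon)
    vowel = unit_consistency(work, "vowel", weighted=weighted)
    body = unit_consistency(work, "body", weighted=weighted)
    opc = mean_opc(work, sample_size=sample_size, seed=seed)
    rows = []
    for i, e in enumerate(work):
        rows.append(
            {
                "orthography": e.orthography,
                "phonology": " ".join(e.phonology),
                "vowel_consistency": vowel.values[i],
                "body_consistency": body.values[i],
                "opc": opc.per_word.get(i, float("nan")),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cross-language comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLanguageSummary:
    """Measure matrix, correlations, and a 2-component PCA across languages."""

    matrix: pd.DataFrame  # languages x measures
    correlations: pd.DataFrame
    loadings: pd.DataFrame  # measures x [PC1, PC2]
    scores: pd.DataFrame  # languages x [PC1, PC2]
    variance_explained: tuple[float, float]
    eigenvalues: tuple[float, ...]
    dropped_measures: tuple[str, ...]


def correlate_and_project(
    reports: Sequence[DepthReport],
    measures: Sequence[str] = DEFAULT_MEASURES,
) -> CrossLanguageSummary:
    """Pearson correlations and a correlation-matrix PCA over languages.

    Measures are standardized (zero mean, unit variance) before the PCA;
    constant or all-missing columns are dropped with a warning.  Signs are
    fixed by forcing each component's largest-magnitude loading positive.
    Needs at least three reports.
    """
    if len(reports) < 3:
        raise MeasureError("correlate_and_project needs at least 3 reports")
    index = [r.language_tag or f"lang{i}" for i, r in enumerate(reports)]
    matrix = pd.DataFrame(
        [r.measure_vector() for r in reports], index=index
    )[list(measures)]
    matrix = matrix.astype(float)
    dropped = tuple(
        c for c in matrix.columns if matrix[c].isna().any() or matrix[c].nunique() <= 1
    )
    if dropped:
        warnings.warn(f"dropping constant/missing measures: {dropped}", stacklevel=2)
    mat = matrix.drop(columns=list(dropped))
    if mat.shape[1] < 2:
        raise MeasureError("fewer than 2 usable measures for the PCA")
    z = (mat - mat.mean()) / mat.std(ddof=1)
    corr = z.corr()
    eigvals, eigvecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    load = eigvecs[:, :2].copy()
    for k in range(2):
        if load[np.argmax(np.abs(load[:, k])), k] < 0:
            load[:, k] = -load[:, k]
    loadings = pd.DataFrame(load, index=mat.columns, columns=["PC1", "PC2"])
    scores = pd.DataFrame(
        z.to_numpy() @ load, index=mat.index, columns=["PC1", "PC2"]
    )
    total = float(eigvals.sum())
    return CrossLanguageSummary(
        matrix=matrix,
        correlations=corr,
        loadings=loadings,
        scores=scores,
        variance_explained=(float(eigvals[0]) / total, float(eigvals[1]) / total),
        eigenvalues=tuple(float(v) for v in eigvals),
        dropped_measures=dropped,
    )


def plot_biplot(summary: CrossLanguageSummary, path) -> None:
    """Save a PCA biplot (loadings as arrows, languages as points) as SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    sc = summary.scores
    ax.scatter(sc["PC1"], sc["PC2"], color="tab:blue")
    for lang, row in sc.iterrows():
        ax.annotate(lang, (row["PC1"], row["PC2"]), fontsize=9)
    scale = float(np.abs(sc.to_numpy()).max() or 1.0)
    for meas, row in summary.loadings.iterrows():
        ax.annotate(
            "",
            xy=(row["PC1"] * scale, row["PC2"] * scale),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:red", alpha=0.7),
        )
        ax.annotate(
            meas,
            (row["PC1"] * scale * 1.05, row["PC2"] * scale * 1.05),
            fontsize=7,
            color="tab:red",
        )
    v1, v2 = summary.variance_explained
    ax.set_xlabel(f"PC1 ({100 * v1:.0f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * v2:.0f}% variance)")
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
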