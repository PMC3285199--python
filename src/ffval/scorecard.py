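"""Force-field scoring: per-test 0-2 scores, 0-6 totals, ranking and trend.

Each force field receives an integer 0-2 for each of three test families —
folded-protein NMR agreement, peptide conformational equilibria, and folding
simulations — with 0 meaning reasonable agreement with experiment and 2
severe discrepancies.  The overall score is their sum (0-6, lower is
better).  The reference scores shipped with the package are expert-assigned
judgements (explicitly subjective); :func:`apply_rubric` offers a
reproducible threshold-based alternative that is clearly labelled as such
and never silently substituted for the reference assignments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import pandas as pd
from scipy import stats

from .exceptions import FfvalError

__all__ = [
    "ScoreCard",
    "RubricThresholds",
    "load_reference_scorecards",
    "aggregate_score",
    "rank_force_fields",
    "score_year_trend",
    "apply_rubric",
    "render_report",
]

TEST_NAMES = ("folded_proteins", "peptides", "folding")


@dataclass(frozen=True)
class ScoreCard:
    """Per-test scores (each 0-2) and their total for one force field."""

    force_field: str
    year: int
    per_test: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.per_test) != 3 or any(s not in (0, 1, 2) for s in self.per_test):
            raise ValueError(f"per_test must be three integers in {{0,1,2}}, got {self.per_test}")

    @property
    def total(self) -> int:
        return aggregate_score(self.per_test)


def aggregate_score(per_test: Sequence[int]) -> int:
    """Sum of the three per-test scores; each component must be in {0, 1, 2}."""
    if len(per_test) != 3:
        raise FfvalError(f"expected three per-test scores, got {len(per_test)}")
    for s in per_test:
        if s not in (0, 1, 2):
            raise FfvalError(f"per-test score {s!r} outside {{0, 1, 2}}")
    return int(sum(per_test))


def load_reference_scorecards(path: str | Path | None = None) -> list[ScoreCard]:
    """Load the packaged (or a user-supplied) score table.

    Columns: ``force_field, year, s_folded, s_peptides, s_folding``.  The
    ``year`` follows the convention of dating each force field by its most
    recently published correction.
    """
    if path is None:
        ref = importlib.resources.files("ffval") / "data" / "forcefield_scores.tsv"
        df = pd.read_csv(ref.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = ["force_field", "year", "s_folded", "s_peptides", "s_folding"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FfvalError(f"score table missing columns {missing}")
    return [
        ScoreCard(
            force_field=row.force_field,
            year=int(row.year),
            per_test=(int(row.s_folded), int(row.s_peptides), int(row.s_folding)),
        )
        for row in df.itertuples()
    ]


def rank_force_fields(cards: Sequence[ScoreCard]) -> list[tuple[int, ScoreCard]]:
    """Cards ordered by ascending total with competition ("1224") ranking.

    Ties share the minimum rank.  Lower totals mean better agreement with
    experiment, so rank 1 is the best force field.
    """
    if not cards:
        raise FfvalError("no scorecards to rank")
    labels = [c.force_field for c in cards]
    if len(set(labels)) != len(labels):
        raise FfvalError("duplicate force-field labels")
    ordered = sorted(cards, key=lambda c: (c.total, c.force_field))
    ranked: list[tuple[int, ScoreCard]] = []
    for i, card in enumerate(ordered):
        if i > 0 and card.total == ordered[i - 1].total:
            rank = ranked[-1][0]
        else:
            rank = i + 1
        ranked.append((rank, card))
    return ranked


def score_year_trend(cards: Sequence[ScoreCard]) -> float:
    """Spearman rank correlation between publication year and total score.

    A negative value means later force fields score better (improvement over
    time).  Degenerate inputs (all totals equal) return 0.0 with a warning.
    """
    years = [c.year for c in cards]
    if len(set(years)) < 3:
        raise FfvalError("score-year trend needs at least 3 distinct years")
    totals = [c.total for c in cards]
    if len(set(totals)) == 1:
        warnings.warn("all totals equal; score-year correlation undefined, returning 0.0",
                      stacklevel=2)
        return 0.0
    rho, _ = stats.spearmanr(years, totals)
    return float(rho)


@dataclass(frozen=True)
class RubricThresholds:
    """Cut-points mapping continuous per-test metrics to score classes.

    For each test, ``(c1, c2)`` with ``c1 < c2``: metric <= c1 scores 0,
    c1 < metric <= c2 scores 1, metric > c2 scores 2 (boundary values fall in
    the lower class).  These cut-points are package-defined conveniences, not
    part of the reference scoring, and reports flag them as such.
    """

    cutpoints: Mapping[str, tuple[float, float]]
    version: str = "ffval-rubric-1"

    def __post_init__(self) -> None:
        for test, (c1, c2) in self.cutpoints.items():
            if not c1 < c2:
                raise ValueError(f"cut-points for {test!r} must be strictly ordered, got {c1}, {c2}")


def apply_rubric(metrics: Mapping[str, float], rubric: RubricThresholds) -> tuple[int, int, int]:
    """Deterministic per-test triple from continuous metrics and cut-points."""
    scores = []
    for test in TEST_NAMES:
        if test not in metrics:
            raise FfvalError(f"missing metric for test {test!r}")
        if test not in rubric.cutpoints:
            raise FfvalError(f"rubric has no cut-points for test {test!r}")
        c1, c2 = rubric.cutpoints[test]
        m = metrics[test]
        scores.append(0 if m <= c1 else (1 if m <= c2 else 2))
    return tuple(scores)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _event_cell(reached_folded: bool, n_fold: int, n_unfold: int) -> str:
    return f"✓ ({n_fold}/{n_unfold})" if reached_folded else "✗"


def render_report(
    out_dir: str | Path,
    panels: pd.DataFrame | None = None,
    curves: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    cards: Sequence[ScoreCard] | None = None,
    provenance: Mapping[str, str] | None = None,
) -> list[Path]:
    """Write the full comparison bundle (CSV tables + Markdown summary).

    ``events`` expects columns ``label, system, n_fold, n_unfold``; the grid
    marks whether the folded state was reached ("check (n_fold/n_unfold)" or
    a cross).  Output is byte-deterministic given identical inputs.
    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    prov_lines = [f"# {k}: {v}" for k, v in sorted((provenance or {}).items())]

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        with open(p, "w") as fh:
            for line in prov_lines:
                fh.write(line + "\n")
            df.to_csv(fh, index=False)
        written.append(p)

    md: list[str] = ["# Force-field validation report", ""]
    md.extend(f"_{line.lstrip('# ')}_" for line in prov_lines)
    md.append("")

    if panels is not None and not panels.empty:
        _write_csv(panels, "agreement_panel.csv")
        md += ["## Observable agreement", "", panels.to_markdown(index=False), ""]

    if curves is not None and not curves.empty:
        _write_csv(curves, "melting_curves.csv")
        md += ["## Melting curves", "", curves.to_markdown(index=False), ""]
    elif curves is not None:
        md += ["## Melting curves", "", "_no melting-curve data supplied_", ""]

    if events is not None and not events.empty:
        ev = events.copy()
        ev["cell"] = [
            _event_cell(bool(r.n_fold > 0), int(r.n_fold), int(r.n_unfold))
            for r in ev.itertuples()
        ]
        _write_csv(ev, "folding_events.csv")
        grid = ev.pivot(index="label", columns="system", values="cell").fillna("✗")
        md += ["## Folding events", "", grid.to_markdown(), ""]

    if cards:
        ranked = rank_force_fields(cards)
        df = pd.DataFrame(
            [
                {
                    "rank": rank,
                    "force_field": c.force_field,
                    "year": c.year,
                    "s_folded": c.per_test[0],
                    "s_peptides": c.per_test[1],
                    "s_folding": c.per_test[2],
                    "total": c.total,
                }
                for rank, c in ranked
            ]
        )
        _write_csv(df, "scorecards.csv")
        md += ["## Force-field scores (lower is better)", "", df.to_markdown(index=False), ""]
        try:
            rho = score_year_trend(cards)
            md.append(f"Spearman correlation between year and total score: {rho:.3f}")
            md.append("")
        except FfvalError:
            md.append("_score-year trend skipped: fewer than 3 distinct years_")
            md.append("")

    report = out_dir / "report.md"
    report.write_text("\n".join(md))
    written.append(report)
    return written
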