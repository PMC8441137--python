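"""Audit-table schema, validation, delimited I/O and count bookkeeping.

An audit dataset couples two tables:

* ``papers`` — one row per surveyed publication, recording its publication
  year, study type (species crossed with design) and the outcome of the
  data-recovery attempt.
* ``results`` — one row per publication in the reproduction subsample,
  recording how many individually citable results were identified and how
  many survived each downstream stage (usable data, clear analysis,
  consistent result). Stages are strictly nested: a result can only be
  checked for analytical clarity if its data were usable, and so on.

Both tables are plain UTF-8 CSV with a header row, one record per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "STUDY_TYPES",
    "RECOVERY_CATEGORIES",
    "RECOVERED_CATEGORIES",
    "RESPONSE_CATEGORIES",
    "AuditError",
    "SchemaError",
    "MonotonicityError",
    "ReferentialIntegrityError",
    "PaperRecord",
    "ResultsRecord",
    "AuditDataset",
    "CountsSummary",
    "read_audit_table",
    "write_audit_table",
    "summarize_counts",
]

#: The four study types: species (human / non-human) crossed with design
#: (experimental / observational). Every audited paper maps to exactly one.
STUDY_TYPES = (
    "human_experimental",
    "human_observational",
    "nonhuman_experimental",
    "nonhuman_observational",
)

#: Outcome categories of a data-recovery attempt.
RECOVERY_CATEGORIES = ("online", "received", "lost", "no_response", "no_request")

#: Categories that count as a successful recovery (stage 1 success).
RECOVERED_CATEGORIES = ("online", "received")

#: Categories in which the contacted author replied at all.
RESPONSE_CATEGORIES = ("received", "lost")

PAPER_COLUMNS = ("paper_id", "pub_year", "study_type", "recovery_category")
RESULTS_COLUMNS = (
    "paper_id",
    "n_results",
    "n_data_usable",
    "n_analysis_clear",
    "n_results_agree",
)


class AuditError(ValueError):
    """Base class for audit-table validation failures."""


class SchemaError(AuditError):
    """A required column is missing or a value is outside its domain."""


class MonotonicityError(AuditError):
    """Stage counts violate the nesting x4 <= x3 <= x2 <= n."""


class ReferentialIntegrityError(AuditError):
    """A results row references a paper that is absent or not recovered."""


@dataclass(frozen=True)
class PaperRecord:
    """One audited publication."""

    paper_id: str
    pub_year: int
    age: int
    study_type: str
    recovery_category: str

    @property
    def recovered(self) -> int:
        return int(self.recovery_category in RECOVERED_CATEGORIES)


@dataclass(frozen=True)
class ResultsRecord:
    """Stage 2-4 counts for one publication of the reproduction subsample.

    ``n`` results were identified; ``x2`` of them had usable data, ``x3`` of
    those had a clear analysis, ``x4`` of those agreed on re-computation.
    """

    paper_id: str
    n: int
    x2: int
    x3: int
    x4: int


@dataclass
class AuditDataset:
    """A validated audit: papers table, results table, reference year.

    ``papers`` carries columns ``paper_id, pub_year, study_type,
    recovery_category`` plus derived ``age`` (reference_year - pub_year) and
    ``recovered`` (0/1). ``results`` carries ``paper_id, n_results,
    n_data_usable, n_analysis_clear, n_results_agree`` and may be empty.
    """

    reference_year: int
    papers: pd.DataFrame
    results: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.results is None:
            self.results = pd.DataFrame(columns=list(RESULTS_COLUMNS))
        self.papers = _normalize_papers(self.papers, self.reference_year)
        self.results = _normalize_results(self.results)
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        papers, results = self.papers, self.results
        if papers["paper_id"].duplicated().any():
            dup = papers.loc[papers["paper_id"].duplicated(), "paper_id"].iloc[0]
            raise ReferentialIntegrityError(f"duplicate paper_id {dup!r}")
        bad_type = ~papers["study_type"].isin(STUDY_TYPES)
        if bad_type.any():
            raise SchemaError(
                f"unknown study_type {papers.loc[bad_type, 'study_type'].iloc[0]!r}"
            )
        bad_cat = ~papers["recovery_category"].isin(RECOVERY_CATEGORIES)
        if bad_cat.any():
            raise SchemaError(
                "unknown recovery_category "
                f"{papers.loc[bad_cat, 'recovery_category'].iloc[0]!r}"
            )
        if (papers["age"] < 0).any():
            pid = papers.loc[papers["age"] < 0, "paper_id"].iloc[0]
            raise SchemaError(
                f"paper {pid!r} published after reference year {self.reference_year}"
            )
        if len(results):
            n = results["n_results"].to_numpy()
            x2 = results["n_data_usable"].to_numpy()
            x3 = results["n_analysis_clear"].to_numpy()
            x4 = results["n_results_agree"].to_numpy()
            ok = (0 <= x4) & (x4 <= x3) & (x3 <= x2) & (x2 <= n) & (n > 0)
            if not ok.all():
                pid = results.loc[~ok, "paper_id"].iloc[0]
                raise MonotonicityError(
                    f"stage counts of paper {pid!r} violate x4 <= x3 <= x2 <= n"
                )
            if results["paper_id"].duplicated().any():
                dup = results.loc[results["paper_id"].duplicated(), "paper_id"].iloc[0]
                raise ReferentialIntegrityError(f"duplicate results row for {dup!r}")
            recovered_ids = set(
                papers.loc[papers["recovered"] == 1, "paper_id"]
            )
            missing = [p for p in results["paper_id"] if p not in recovered_ids]
            if missing:
                raise ReferentialIntegrityError(
                    f"results row for {missing[0]!r} has no recovered paper"
                )

    # -- record accessors ----------------------------------------------

    def paper_records(self) -> list[PaperRecord]:
        return [
            PaperRecord(
                paper_id=r.paper_id,
                pub_year=int(r.pub_year),
                age=int(r.age),
                study_type=r.study_type,
                recovery_category=r.recovery_category,
            )
            for r in self.papers.itertuples(index=False)
        ]

    def results_records(self) -> list[ResultsRecord]:
        return [
            ResultsRecord(
                paper_id=r.paper_id,
                n=int(r.n_results),
                x2=int(r.n_data_usable),
                x3=int(r.n_analysis_clear),
                x4=int(r.n_results_agree),
            )
            for r in self.results.itertuples(index=False)
        ]

    def paper_ages(self) -> dict[str, int]:
        """Mapping paper_id -> years since publication."""
        return dict(zip(self.papers["paper_id"], self.papers["age"].astype(int)))

    def equals(self, other: "AuditDataset") -> bool:
        return (
            self.reference_year == other.reference_year
            and self.papers.reset_index(drop=True).equals(
                other.papers.reset_index(drop=True)
            )
            and self.results.reset_index(drop=True).equals(
                other.results.reset_index(drop=True)
            )
        )


def _normalize_papers(papers: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    for col in PAPER_COLUMNS:
        if col not in papers.columns:
            raise SchemaError(f"papers table is missing column {col!r}")
    out = papers.loc[:, list(PAPER_COLUMNS)].copy()
    out["paper_id"] = out["paper_id"].astype(str)
    out["pub_year"] = out["pub_year"].astype(int)
    out["study_type"] = out["study_type"].astype(str)
    out["recovery_category"] = out["recovery_category"].astype(str)
    out["age"] = reference_year - out["pub_year"]
    out["recovered"] = out["recovery_category"].isin(RECOVERED_CATEGORIES).astype(int)
    return out.reset_index(drop=True)


def _normalize_results(results: pd.DataFrame) -> pd.DataFrame:
    for col in RESULTS_COLUMNS:
        if col not in results.columns:
            raise SchemaError(f"results table is missing column {col!r}")
    out = results.loc[:, list(RESULTS_COLUMNS)].copy()
    out["paper_id"] = out["paper_id"].astype(str)
    for col in RESULTS_COLUMNS[1:]:
        out[col] = out[col].astype(int)
    return out.reset_index(drop=True)


def read_audit_table(
    paper_path: str | Path,
    results_path: str | Path | None = None,
    reference_year: int = 2019,
) -> AuditDataset:
    """Read and validate papers.csv (+ optional results.csv).

    Raises :class:`SchemaError`, :class:`MonotonicityError` or
    :class:`ReferentialIntegrityError` with the offending column or paper_id
    named in the message.
    """
    papers = pd.read_csv(paper_path, dtype={"paper_id": str})
    if results_path is not None:
        results = pd.read_csv(results_path, dtype={"paper_id": str})
    else:
        results = pd.DataFrame(columns=list(RESULTS_COLUMNS))
    return AuditDataset(reference_year=reference_year, papers=papers, results=results)


def write_audit_table(
    ds: AuditDataset, paper_path: str | Path, results_path: str | Path
) -> None:
    """Write the two CSV tables; derived columns (age, recovered) are not stored."""
    ds.papers.loc[:, list(PAPER_COLUMNS)].to_csv(paper_path, index=False)
    ds.results.loc[:, list(RESULTS_COLUMNS)].to_csv(results_path, index=False)


def papers_from_margins(
    category_counts: dict[str, int],
    reference_year: int = 2019,
    pub_year: int = 2000,
    study_type: str = "human_experimental",
) -> pd.DataFrame:
    """Encode published audit margins as a papers table.

    Builds one row per paper with the given recovery-category counts;
    publication year and study type are fillers, for bookkeeping checks that
    depend only on the category margins.
    """
    rows = []
    i = 0
    for cat, count in category_counts.items():
        if cat not in RECOVERY_CATEGORIES:
            raise SchemaError(f"unknown recovery_category {cat!r}")
        for _ in range(count):
            rows.append((f"m{i:04d}", pub_year, study_type, cat))
            i += 1
    return pd.DataFrame(rows, columns=list(PAPER_COLUMNS))


@dataclass
class CountsSummary:
    """Margins of the audit: recovery categories, study types, stage totals."""

    n_papers: int
    by_category: dict[str, int]
    by_type: dict[str, int]
    recovered: int
    recovered_fraction: float
    responded: int
    responded_fraction: float
    n_results_papers: int
    n_results: int
    n_data_usable: int
    n_analysis_clear: int
    n_results_agree: int

    def as_text(self) -> str:
        lines = [f"papers: {self.n_papers}"]
        for cat in RECOVERY_CATEGORIES:
            lines.append(f"recovery_category.{cat}: {self.by_category.get(cat, 0)}")
        lines.append(
            f"recovered: {self.recovered} ({100 * self.recovered_fraction:.1f}%)"
        )
        lines.append(
            f"responded: {self.responded} ({100 * self.responded_fraction:.1f}%)"
        )
        for st in STUDY_TYPES:
            lines.append(f"study_type.{st}: {self.by_type.get(st, 0)}")
        lines.append(f"results_papers: {self.n_results_papers}")
        lines.append(f"results_identified: {self.n_results}")
        lines.append(f"results_data_usable: {self.n_data_usable}")
        lines.append(f"results_analysis_clear: {self.n_analysis_clear}")
        lines.append(f"results_agree: {self.n_results_agree}")
        return "\n".join(lines)


def summarize_counts(ds: AuditDataset) -> CountsSummary:
    """Totals per recovery category and study type, plus stage result totals.

    ``recovered`` counts papers whose data were obtained online or received
    from authors; ``responded`` counts papers whose authors replied at all
    (data received, or reported lost/inaccessible).
    """
    papers = ds.papers
    by_category = {
        cat: int((papers["recovery_category"] == cat).sum())
        for cat in RECOVERY_CATEGORIES
    }
    by_type = {st: int((papers["study_type"] == st).sum()) for st in STUDY_TYPES}
    n_papers = len(papers)
    recovered = sum(by_category[c] for c in RECOVERED_CATEGORIES)
    responded = sum(by_category[c] for c in RESPONSE_CATEGORIES)
    res = ds.results
    return CountsSummary(
        n_papers=n_papers,
        by_category=by_category,
        by_type=by_type,
        recovered=recovered,
        recovered_fraction=recovered / n_papers if n_papers else 0.0,
        responded=responded,
        responded_fraction=responded / n_papers if n_papers else 0.0,
        n_results_papers=len(res),
        n_results=int(res["n_results"].sum()) if len(res) else 0,
        n_data_usable=int(res["n_data_usable"].sum()) if len(res) else 0,
        n_analysis_clear=int(res["n_analysis_clear"].sum()) if len(res) else 0,
        n_results_agree=int(res["n_results_agree"].sum()) if len(res) else 0,
    )
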