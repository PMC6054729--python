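"""End-to-end orchestration: summaries, partial tests, NPC, Holm, reports.

One seed drives a single unit-level assignment sequence shared by all K
partial tests (restricted per variable to its complete cases when values are
missing), so the nonparametric combination sees the joint permutation
distribution.  Reports come in three styles: a descriptive table with raw
p-values and the combined p-value, a step-down table with ranks and adjusted
p-values, and a lossless machine-readable form.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import CohortTable, VariableSpec, extract_complete, summarize_variable
from .errors import ConfigurationError, DegenerateVariableError
from .multiplicity import HolmResult, holm_report
from .npc_combination import COMBINING_METHODS, NPCResult, npc_global_test
from .partial_tests import PartialTestResult, partial_test
from .permutation_engine import PermutationScheme, generate_assignments

logger = logging.getLogger("npcperm")

__version__ = "0.1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of one analysis run."""

    scheme: PermutationScheme = field(default_factory=PermutationScheme)
    method: str = "fisher"
    alpha: float = 0.05
    cap: float = 1.0
    report_precision: int = 4
    studentize: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.report_precision < 1:
            raise ConfigurationError("report_precision must be >= 1")
        if self.method not in COMBINING_METHODS:
            raise ConfigurationError(f"method must be one of {COMBINING_METHODS}")


@dataclass
class AnalysisReport:
    """Everything one run produced, keyed consistently by variable."""

    summaries: dict[str, dict]
    partials: list[PartialTestResult]
    npc: NPCResult
    holm: list[HolmResult]
    metadata: dict

    @property
    def variables(self) -> list[str]:
        return [p.variable for p in self.partials]

    def holm_significant(self) -> list[str]:
        return [h.variable for h in self.holm if h.significant]


def run_analysis(
    table: CohortTable,
    specs: list[VariableSpec] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the complete two-group comparison on a cohort.

    Deterministic: identical (table, config) give a bit-identical report.
    """
    config = config or AnalysisConfig()
    specs = specs if specs is not None else table.specs
    if not specs:
        raise ConfigurationError("need at least one variable")
    scheme = config.scheme
    logger.info(
        "analysis: K=%d variables, n1=%d, n2=%d, B=%d, seed=%d, method=%s",
        len(specs), table.n1, table.n2, scheme.n_permutations, scheme.seed,
        config.method,
    )

    # one unit-level assignment sequence shared by every variable; columns
    # indexed by unit in table order, row 0 = the observed grouping
    order = np.argsort(table.groups, kind="stable")
    a_sorted = generate_assignments(table.n1, table.n2, scheme)
    assignments = np.empty_like(a_sorted)
    assignments[:, order] = a_sorted
    exact = scheme.is_exact(table.n1, table.n2)

    summaries: dict[str, dict] = {}
    partials: list[PartialTestResult] = []
    for spec in specs:
        try:
            x1, x2 = extract_complete(table, spec.name)
            summaries[spec.name] = summarize_variable(x1, x2, spec)
        except DegenerateVariableError as exc:
            raise DegenerateVariableError(f"{spec.name!r}: {exc}") from exc
        res = partial_test(
            table, spec.name, scheme,
            assignments=assignments, studentize=config.studentize,
        )
        res.exact = exact and not res.degenerate
        logger.info(
            "partial %-32s n=%d/%d raw p=%.4g%s", spec.name, res.n1, res.n2,
            res.raw_p, " (degenerate)" if res.degenerate else "",
        )
        partials.append(res)

    npc = npc_global_test(partials, method=config.method)
    holm = holm_report(
        [p.variable for p in partials], [p.raw_p for p in partials],
        alpha=config.alpha, cap=config.cap,
    )
    metadata = {
        "version": __version__,
        "seed": scheme.seed,
        "B": npc.n_assignments,
        "exact": exact,
        "method": config.method,
        "alpha": config.alpha,
        "cap": config.cap,
        "studentize": config.studentize,
        "n1": table.n1,
        "n2": table.n2,
        "group_labels": dict(table.group_labels),
        "complete_cases": {p.variable: (p.n1, p.n2) for p in partials},
    }
    return AnalysisReport(
        summaries=summaries, partials=partials, npc=npc, holm=holm,
        metadata=metadata,
    )


def adjust_only(
    variables: list[str], raw_ps, alpha: float = 0.05, cap: float = 1.0
) -> list[HolmResult]:
    """Multiplicity stage alone, from a bare vector of raw p-values.

    The step-down adjusted values are a pure function of the raw values, so
    published per-variable p-values can be re-adjusted without any cohort.
    """
    return holm_report(variables, raw_ps, alpha=alpha, cap=cap)


def format_pvalue(p: float, b: int, precision: int = 4, floor_tol: float = 1e-15) -> str:
    """Fixed-precision p-value rendering.

    A p-value at its 1/B resolution floor means "no permutation beat the
    observed statistic"; table-style rendering reports it as below printable
    resolution (all zeros), the convention of the software the motivating
    study used.
    """
    if b > 0 and p <= 1.0 / b + floor_tol:
        return f"{0.0:.{precision}f}"
    return f"{p:.{precision}f}"


def render_report(report: AnalysisReport, style: str = "table2") -> str:
    """Render a report as text: 'table1', 'table2' or 'machine'."""
    if style == "table1":
        return _render_table1(report)
    if style == "table2":
        return _render_table2(report)
    if style == "machine":
        return _render_machine(report)
    raise ConfigurationError(f"unknown style {style!r}")


def _render_table1(report: AnalysisReport) -> str:
    prec = 4
    b = report.npc.n_assignments
    out = io.StringIO()
    out.write(f"{'Variable':<34}{'Group 1':>22}{'Group 2':>22}{'p-value':>10}\n")
    for p in report.partials:
        s = report.summaries[p.variable]
        if s["kind"] == "numeric":
            cells = []
            for g in (0, 1):
                sd = s["sd"][g]
                cells.append(
                    f"{s['mean'][g]:.2f} ± {sd:.2f}" if sd is not None
                    else f"{s['mean'][g]:.2f} ± NA"
                )
        else:
            pct = s["percent"]
            cells = [
                " / ".join(f"{pct[lev][g]:.1f}" for lev in pct) for g in (0, 1)
            ]
        out.write(
            f"{p.variable:<34}{cells[0]:>22}{cells[1]:>22}"
            f"{p.raw_p:>10.{prec}f}\n"
        )
    out.write(
        f"{'COMBINED p-value':<34}{'':>22}{'':>22}"
        f"{format_pvalue(report.npc.combined_p, b, prec):>10}\n"
    )
    return out.getvalue()


def _render_table2(report: AnalysisReport) -> str:
    prec = 4
    out = io.StringIO()
    out.write(f"{'Variable':<34}{'Raw p':>8}{'i':>5}{'Adj. p':>9}  \n")
    for h in report.holm:
        mark = " *" if h.significant else ""
        out.write(
            f"{h.variable:<34}{h.raw_p:>8.{prec}f}{h.rank_i:>5}"
            f"{h.adj_p:>9.{prec}f}{mark}\n"
        )
    alpha = report.metadata["alpha"]
    out.write(f"(* Holm-significant at alpha = {alpha})\n")
    return out.getvalue()


def _render_machine(report: AnalysisReport) -> str:
    """Lossless tab-separated rendering; floats written with repr precision."""
    out = io.StringIO()
    for k, v in sorted(report.metadata.items()):
        if k in ("group_labels", "complete_cases"):
            continue
        out.write(f"# {k}={v!r}\n")
    out.write(f"# combined_p={report.npc.combined_p!r}\n")
    out.write(f"# psi_obs={report.npc.psi_obs!r}\n")
    out.write("variable\traw_p\tt_obs\trank_i\tadj_p\tsignificant\tn1\tn2\n")
    holm_by_var = {h.variable: h for h in report.holm}
    for p in report.partials:
        h = holm_by_var[p.variable]
        out.write(
            f"{p.variable}\t{p.raw_p!r}\t{p.t_obs!r}\t{h.rank_i}\t"
            f"{h.adj_p!r}\t{int(h.significant)}\t{p.n1}\t{p.n2}\n"
        )
    return out.getvalue()


def parse_machine_report(text: str) -> dict:
    """Parse a machine-style rendering back into metadata + per-variable rows."""
    meta: dict = {}
    rows: list[dict] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("# "):
            key, _, val = line[2:].partition("=")
            try:
                import ast

                meta[key] = ast.literal_eval(val)
            except (ValueError, SyntaxError):
                meta[key] = val
            continue
        if header is None:
            header = line.split("\t")
            continue
        cells = line.split("\t")
        row: dict = {"variable": cells[0]}
        for name, cell in zip(header[1:], cells[1:]):
            row[name] = float(cell) if "." in cell or "e" in cell else int(cell)
        rows.append(row)
    return {"metadata": meta, "rows": rows}
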