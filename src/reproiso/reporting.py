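"""End-to-end pipeline runs and table rendering.

``run_pipeline`` reads a ``key=value`` config, runs whichever stages have
inputs (mating trials, crosses, alignment) and collects results plus a list
of data-quality warnings.  When a transcription of published statistics is
supplied, every recomputed value is compared with the printed one at the
printed precision and any disagreement beyond one unit in the last printed
digit becomes a warning — values are reported side by side, never silently
corrected.

``render_tables`` writes the results as CSV and human-readable markdown
whose column order mirrors the published tables; output is deterministic,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .crosses import FertilityResult, analyze_crosses
from .divergence import (
    DistanceMatrix,
    HaplotypeNetwork,
    build_network,
    collapse_haplotypes,
    group_divergence_matrix,
)
from .io_formats import (
    DataQualityWarning,
    read_config,
    read_cross_records,
    read_fasta_alignment,
    read_group_map,
    read_mating_trials,
)
from .mating import IsolationResult, analyze_table

__all__ = [
    "RunReport",
    "run_pipeline",
    "render_tables",
    "round_half_away",
    "fmt",
    "printed_tolerance",
    "matches_printed",
    "compare_isolation_to_printed",
    "compare_crosses_to_printed",
]


def round_half_away(x: float, digits: int = 2) -> float:
    """Round with halves away from zero (the convention of printed tables)."""
    factor = 10.0 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def fmt(x: float | None, digits: int = 2) -> str:
    if x is None:
        return "—"
    return f"{round_half_away(x, digits):.{digits}f}"


def printed_tolerance(printed: str) -> float:
    """One unit in the last printed decimal digit.

    This accepts both round-half-away and truncation conventions, either of
    which appears in published tables.
    """
    printed = printed.strip()
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 10.0 ** -decimals


def matches_printed(value: float, printed: str) -> bool:
    return abs(value - float(printed)) <= printed_tolerance(printed) + 1e-12


@dataclass
class RunReport:
    isolation_table: list[IsolationResult] = field(default_factory=list)
    fertility_table: list[FertilityResult] = field(default_factory=list)
    divergence: DistanceMatrix | None = None
    network: HaplotypeNetwork | None = None
    warnings: list[str] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)


def compare_isolation_to_printed(
    results: list[IsolationResult], printed: pd.DataFrame
) -> list[str]:
    """Flag every recomputed isolation statistic that disagrees with print."""
    out: list[str] = []
    by_pair = {frozenset(r.pair): r for r in results}
    stats = [
        ("chi2", lambda r: r.chi2),
        ("I", lambda r: r.I),
        ("SE(I)", lambda r: r.se_I),
        ("I1", lambda r: r.I1),
        ("SE(I1)", lambda r: r.se_I1),
        ("I2", lambda r: r.I2),
        ("SE(I2)", lambda r: r.se_I2),
    ]
    columns = ["chi2", "I", "se_I", "I1", "se_I1", "I2", "se_I2"]
    for _, row in printed.iterrows():
        key = frozenset((row["strain_a"], row["strain_b"]))
        res = by_pair.get(key)
        if res is None:
            out.append(f"{row['strain_a']}-{row['strain_b']}: printed row has "
                       "no recomputed counterpart")
            continue
        if res.n_mismatch:
            out.append(
                f"{res.pair[0]}-{res.pair[1]}: printed N {res.n_reported} "
                f"differs from count sum {res.n}"
            )
        for (name, getter), col in zip(stats, columns):
            printed_value = row[col]
            if printed_value in (None, ""):
                continue
            value = getter(res)
            if value is None or not matches_printed(value, printed_value):
                shown = "undefined" if value is None else f"{value:.4f}"
                out.append(
                    f"{res.pair[0]}-{res.pair[1]}: printed {name} "
                    f"{printed_value} vs recomputed {shown} (beyond printed "
                    "precision)"
                )
    return out


def compare_crosses_to_printed(
    results: list[FertilityResult], printed: pd.DataFrame
) -> list[str]:
    out: list[str] = []
    by_cross = {r.cross: r for r in results}
    for _, row in printed.iterrows():
        res = by_cross.get((row["mother"], row["father"]))
        if res is None:
            out.append(f"{row['mother']}x{row['father']}: printed row has no "
                       "recomputed counterpart")
            continue
        if not matches_printed(res.chi2_sex, row["chi2"]):
            out.append(
                f"{res.cross[0]}x{res.cross[1]}: printed sex-ratio chi2 "
                f"{row['chi2']} vs recomputed {res.chi2_sex:.4f} (beyond "
                "printed precision)"
            )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path) -> RunReport:
    """Run every stage named in the config and collect results and warnings.

    Recognised keys: ``trials``, ``crosses``, ``alignment``, ``group_map``,
    ``printed_isolation``, ``printed_crosses``, ``out_dir``, ``digits``,
    ``seed``, ``connection_limit``.  At least one of the three input tables
    must be present.
    """
    config_path = Path(config_path)
    config = read_config(config_path)
    inputs = [k for k in ("trials", "crosses", "alignment") if k in config]
    if not inputs:
        raise KeyError(
            "configuration names no inputs: need at least one of "
            "trials, crosses, alignment"
        )
    base = config_path.parent

    def resolve(key: str) -> Path:
        p = Path(config[key])
        return p if p.is_absolute() else base / p

    report = RunReport()
    report.meta["version"] = __version__
    report.meta["seed"] = config.get("seed", "0")
    for key in ("trials", "crosses", "alignment", "group_map",
                "printed_isolation", "printed_crosses"):
        if key in config:
            report.meta[f"sha256:{key}"] = _sha256(resolve(key))

    if "trials" in config:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DataQualityWarning)
            trials = read_mating_trials(resolve("trials"))
        report.isolation_table = analyze_table(trials)
        if "printed_isolation" in config:
            printed = pd.read_csv(resolve("printed_isolation"), dtype=str)
            report.warnings.extend(
                compare_isolation_to_printed(report.isolation_table, printed)
            )
        else:
            report.warnings.extend(
                str(w.message) for w in caught
                if issubclass(w.category, DataQualityWarning)
            )

    if "crosses" in config:
        crosses = read_cross_records(resolve("crosses"))
        report.fertility_table = analyze_crosses(crosses)
        if "printed_crosses" in config:
            printed = pd.read_csv(resolve("printed_crosses"), dtype=str)
            report.warnings.extend(
                compare_crosses_to_printed(report.fertility_table, printed)
            )

    if "alignment" in config:
        group_map = None
        if "group_map" in config:
            group_map = read_group_map(resolve("group_map"))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DataQualityWarning)
            aln = read_fasta_alignment(resolve("alignment"), group_map=group_map)
        report.warnings.extend(
            str(w.message) for w in caught
            if issubclass(w.category, DataQualityWarning)
        )
        report.divergence = group_divergence_matrix(aln)
        limit = config.get("connection_limit")
        haps = collapse_haplotypes(aln)
        report.network = build_network(
            haps, connection_limit=int(limit) if limit else None
        )
    return report


def _isolation_frame(results: list[IsolationResult], digits: int) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "strain_a": r.pair[0], "strain_b": r.pair[1], "n": r.n,
            "chi2": fmt(r.chi2, digits), "df": r.df,
            "p_value": fmt(r.p_value, 4),
            "I": fmt(r.I, digits), "se_I": fmt(r.se_I, digits),
            "sig_I": int(r.significant_I),
            "I1": fmt(r.I1, digits), "se_I1": fmt(r.se_I1, digits),
            "sig_I1": "" if r.significant_I1 is None else int(r.significant_I1),
            "I2": fmt(r.I2, digits), "se_I2": fmt(r.se_I2, digits),
            "sig_I2": "" if r.significant_I2 is None else int(r.significant_I2),
        })
    return pd.DataFrame(rows)


def _fertility_frame(results: list[FertilityResult], digits: int) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "mother": r.cross[0], "father": r.cross[1],
            "total_offspring": r.total_offspring,
            "chi2_sex": fmt(r.chi2_sex, digits), "df": r.df,
            "p_value": fmt(r.p_value, 4),
            "motile_fraction": fmt(r.motile_fraction, digits),
            "ci_low": fmt(r.motile_ci[0], digits) if r.motile_ci else "—",
            "ci_high": fmt(r.motile_ci[1], digits) if r.motile_ci else "—",
            "category": r.category,
        })
    return pd.DataFrame(rows)


def _star(flag: bool | None) -> str:
    return "*" if flag else ""


def _isolation_markdown(results: list[IsolationResult], digits: int) -> str:
    lines = [
        "| A | B | N | A×A | A×B | B×A | B×B | χ² | p | I (SE) | I1 (SE) | I2 (SE) |",
        "|---|---|---|----|----|----|----|----|---|--------|---------|---------|",
    ]
    for r in results:
        def idx(i, se, sig):
            if i is None:
                return "—"
            return f"{fmt(i, digits)} ({fmt(se, digits)}){_star(sig)}"
        lines.append(
            f"| {r.pair[0]} | {r.pair[1]} | {r.n} | — | — | — | — | "
            f"{fmt(r.chi2, digits)} | {fmt(r.p_value, 4)} | "
            f"{idx(r.I, r.se_I, r.significant_I)} | "
            f"{idx(r.I1, r.se_I1, r.significant_I1)} | "
            f"{idx(r.I2, r.se_I2, r.significant_I2)} |"
        )
    return "\n".join(lines) + "\n"


def _fertility_markdown(results: list[FertilityResult], digits: int) -> str:
    lines = [
        "| Mother | Father | Offspring | χ² sex | p | Motile | 95% CI | Category |",
        "|--------|--------|-----------|--------|---|--------|--------|----------|",
    ]
    for r in results:
        ci = (f"[{fmt(r.motile_ci[0], digits)}, {fmt(r.motile_ci[1], digits)}]"
              if r.motile_ci else "—")
        lines.append(
            f"| {r.cross[0]} | {r.cross[1]} | {r.total_offspring} | "
            f"{fmt(r.chi2_sex, digits)} | {fmt(r.p_value, 4)} | "
            f"{fmt(r.motile_fraction, digits)} | {ci} | {r.category} |"
        )
    return "\n".join(lines) + "\n"


def network_to_nexus(network: HaplotypeNetwork) -> str:
    """A minimal NEXUS network block (nodes with frequencies, step edges)."""
    lines = ["#NEXUS", "", "BEGIN NETWORK;"]
    lines.append(
        f"DIMENSIONS nvertices={len(network.nodes)} nedges={len(network.edges)};"
    )
    lines.append("VERTICES")
    for i, hap in enumerate(network.nodes, start=1):
        lines.append(f"  {i} {hap.id} freq={hap.frequency},")
    lines.append(";")
    lines.append("EDGES")
    for i, (u, v, steps) in enumerate(network.edges, start=1):
        lines.append(f"  {i} {u} {v} steps={steps},")
    lines.append(";")
    lines.append("END;")
    return "\n".join(lines) + "\n"


def render_tables(report: RunReport, out_dir: str | Path, digits: int = 2) -> list[Path]:
    """Write CSV + markdown tables and the run log; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text, encoding="utf-8")
        written.append(path)

    if report.isolation_table:
        frame = _isolation_frame(report.isolation_table, digits)
        write("isolation.csv", frame.to_csv(index=False))
        write("isolation.md", _isolation_markdown(report.isolation_table, digits))
    if report.fertility_table:
        frame = _fertility_frame(report.fertility_table, digits)
        write("crosses.csv", frame.to_csv(index=False))
        write("crosses.md", _fertility_markdown(report.fertility_table, digits))
    if report.divergence is not None:
        frame = report.divergence.to_dataframe().round(digits)
        write("divergence.csv", frame.to_csv())
    if report.network is not None:
        edges = "\n".join(
            f"{u}\t{v}\t{steps}" for u, v, steps in report.network.edges
        )
        members = "\n".join(
            f"{h.id}\t{h.frequency}\t{';'.join(h.members)}"
            for h in report.network.nodes
        )
        write("network_edges.tsv", "from\tto\tsteps\n" + edges + ("\n" if edges else ""))
        write("network_nodes.tsv", "haplotype\tfrequency\tmembers\n" + members + "\n")
        write("network.nex", network_to_nexus(report.network))
    log = [f"{k}={v}" for k, v in sorted(report.meta.items())]
    log.append(f"warnings={len(report.warnings)}")
    write("run.log", "\n".join(log) + "\n")
    write(
        "warnings.txt",
        "\n".join(report.warnings) + ("\n" if report.warnings else ""),
    )
    return written
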