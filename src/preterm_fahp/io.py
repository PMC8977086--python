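"""File formats: hierarchy configuration, matrix CSV, case CSV, reports.

All files are UTF-8 text.  CSVs are comma-separated with a mandatory
header row and decimal points.  The hierarchy configuration is JSON
(YAML accepted as a convenience alias by file extension), holding the
goal, the linguistic scales as ordered ``{label, a, m, b}`` lists, and
the dimension/factor tree with weights.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, MatrixError
from .fahp import FuzzyPairwiseMatrix
from .fuzzy import (
    LinguisticScale,
    LinguisticTerm,
    TFN,
    default_case_scale,
    default_comparison_scale,
)
from .model import (
    CaseAssessment,
    Dimension,
    ExpertCaseJudgment,
    Factor,
    RiskHierarchy,
)
from .validate import ValidationReport

__all__ = [
    "load_hierarchy_config",
    "save_hierarchy_config",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_cases_csv",
    "write_cases_csv",
    "write_assessments_csv",
    "write_validation_report",
]

_CSV_RECIP_TOL = 1e-6


# ---------------------------------------------------------------------
# Hierarchy configuration
# ---------------------------------------------------------------------

def _scale_to_dict(scale: LinguisticScale) -> dict:
    return {
        "domain": list(scale.domain),
        "terms": [
            {"label": t.label, "a": t.tfn.a, "m": t.tfn.m, "b": t.tfn.b}
            for t in scale.terms
        ],
        "aliases": {
            k: [v.a, v.m, v.b] for k, v in scale.aliases.items()
        },
    }


def _scale_from_dict(data: dict, where: str) -> LinguisticScale:
    try:
        terms = [
            LinguisticTerm(
                str(t["label"]),
                TFN(float(t["a"]), float(t["m"]), float(t["b"])),
            )
            for t in data["terms"]
        ]
        domain = tuple(float(x) for x in data.get("domain", (0.0, 1.0)))
        aliases = {
            str(k): TFN(*map(float, v))
            for k, v in data.get("aliases", {}).items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed scale definition at {where}: {exc}")
    return LinguisticScale(terms, domain=domain, aliases=aliases)


def save_hierarchy_config(
    path,
    hierarchy: RiskHierarchy,
    scales: dict[str, LinguisticScale] | None = None,
) -> None:
    """Serialize a hierarchy (and its scales) to JSON or YAML."""
    scales = scales or {
        "case": default_case_scale(),
        "comparison": default_comparison_scale(),
    }
    payload = {
        "goal": hierarchy.goal,
        "scales": {name: _scale_to_dict(s) for name, s in scales.items()},
        "dimensions": [
            {
                "name": d.name,
                "weight": d.weight,
                "factors": [
                    {"name": f.name, "weight": f.local_weight}
                    for f in d.factors
                ],
            }
            for d in hierarchy.dimensions
        ],
    }
    path = Path(path)
    text = (
        yaml.safe_dump(payload, sort_keys=False)
        if path.suffix in (".yaml", ".yml")
        else json.dumps(payload, indent=2)
    )
    path.write_text(text, encoding="utf-8")


def load_hierarchy_config(path):
    """Load ``(hierarchy, scales)`` from a JSON/YAML configuration file.

    Weight-sum and scale-ordering violations raise :class:`ConfigError`
    (or the underlying hierarchy/scale error) naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}")
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("goal", "dimensions"):
        if key not in data:
            raise ConfigError(f"{path}: missing required field {key!r}")
    scales = {
        name: _scale_from_dict(sd, f"{path}:scales.{name}")
        for name, sd in data.get("scales", {}).items()
    }
    scales.setdefault("case", default_case_scale())
    scales.setdefault("comparison", default_comparison_scale())
    dims = []
    for i, d in enumerate(data["dimensions"]):
        where = f"{path}:dimensions[{i}]"
        try:
            name = str(d["name"])
            weight = float(d["weight"])
            factors = tuple(
                Factor(str(f["name"]), float(f["weight"]))
                for f in d["factors"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed dimension at {where}: {exc}")
        dims.append(Dimension(name, weight, factors))
    hierarchy = RiskHierarchy(goal=str(data["goal"]), dimensions=tuple(dims))
    return hierarchy, scales


# ---------------------------------------------------------------------
# Matrix CSV (long format)
# ---------------------------------------------------------------------

def _parse_cell(cell: str, scale: LinguisticScale, row_no: int) -> TFN:
    cell = cell.strip()
    if ";" in cell:
        parts = cell.split(";")
        if len(parts) != 3:
            raise MatrixError(
                f"row {row_no}: expected 'a;m;b' triple, got {cell!r}"
            )
        try:
            return TFN(*(float(p) for p in parts))
        except ValueError as exc:
            raise MatrixError(f"row {row_no}: bad triple {cell!r}: {exc}")
    try:
        return scale.tfn_for(cell)
    except Exception:
        raise MatrixError(
            f"row {row_no}: {cell!r} is neither an 'a;m;b' triple nor a "
            f"label of the comparison scale {list(scale.labels)}"
        )


def read_matrix_csv(path, scale: LinguisticScale) -> FuzzyPairwiseMatrix:
    """Read a fuzzy pairwise matrix from long-format CSV.

    Header ``row_label,col_label,value``; cells are either linguistic
    labels of ``scale`` or explicit ``a;m;b`` triples.  The upper
    triangle is required, the lower derived; if both halves are present
    they are checked for reciprocity (tolerance 1e-6) with the row
    number reported on violation.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixError(f"{path}: empty matrix file")
        if [h.strip().lower() for h in header[:2]] != ["row_label", "col_label"]:
            raise MatrixError(
                f"{path}: header must start with 'row_label,col_label', "
                f"got {header}"
            )
        labels: list[str] = []
        cells: dict[tuple[str, str], tuple[TFN, int]] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise MatrixError(
                    f"{path} row {row_no}: expected 3 columns, got {row}"
                )
            r, c = row[0].strip(), row[1].strip()
            for lab in (r, c):
                if lab not in labels:
                    labels.append(lab)
            cells[(r, c)] = (_parse_cell(row[2], scale, row_no), row_no)
    if not cells:
        raise MatrixError(f"{path}: no comparisons found")
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    one = TFN(1.0, 1.0, 1.0)
    grid: list[list[TFN | None]] = [
        [one if i == j else None for j in range(n)] for i in range(n)
    ]
    for (r, c), (t, row_no) in cells.items():
        i, j = idx[r], idx[c]
        if i == j:
            if t.as_tuple() != (1.0, 1.0, 1.0):
                raise MatrixError(
                    f"{path} row {row_no}: diagonal entry must be (1,1,1)"
                )
            continue
        if grid[i][j] is not None and i != j:
            # already filled via the mirror cell: the stored value must
            # match this one (the mirror was stored as the reciprocal)
            existing = grid[i][j]
            if any(
                abs(x - y) > _CSV_RECIP_TOL
                for x, y in zip(existing.as_tuple(), t.as_tuple())
            ):
                raise MatrixError(
                    f"{path} row {row_no}: entry ({r},{c}) is not the "
                    f"reciprocal of its mirror cell (tolerance "
                    f"{_CSV_RECIP_TOL:g})"
                )
            continue
        grid[i][j] = t
        if grid[j][i] is None:
            grid[j][i] = t.inverse()
    missing = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if grid[i][j] is None
    ]
    if missing:
        raise MatrixError(f"{path}: missing comparisons for pairs {missing}")
    return FuzzyPairwiseMatrix(labels, grid)


def write_matrix_csv(path, matrix: FuzzyPairwiseMatrix) -> None:
    """Write the upper triangle of a fuzzy matrix as ``a;m;b`` triples."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_label", "col_label", "value"])
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                t = matrix.entry(i, j)
                writer.writerow(
                    [
                        matrix.labels[i],
                        matrix.labels[j],
                        f"{t.a!r};{t.m!r};{t.b!r}",
                    ]
                )


# ---------------------------------------------------------------------
# Case-judgment CSV
# ---------------------------------------------------------------------

_CASE_COLUMNS = ["case_id", "expert_id", "factor", "label"]


def read_cases_csv(path, scale: LinguisticScale) -> list[ExpertCaseJudgment]:
    """Read per-case, per-expert linguistic judgments.

    Header ``case_id,expert_id,factor,label``; unknown labels are
    reported with their row number.  Rows with factor ``"overall"``
    carry the expert's holistic diagnosis.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ConfigError(f"{path}: empty case file")
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    for pos, lab in enumerate(df["label"]):
        if lab not in scale:
            raise ConfigError(
                f"{path} row {pos + 2}: unknown judgment label {lab!r}; "
                f"scale terms are {list(scale.labels)}"
            )
    records: dict[tuple[str, str], dict[str, str]] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        key = (row.case_id, row.expert_id)
        if key not in records:
            records[key] = {}
            order.append(key)
        records[key][row.factor] = row.label
    return [
        ExpertCaseJudgment(case_id=c, expert_id=e, judgments=records[(c, e)])
        for c, e in order
    ]


def write_cases_csv(path, judgments: list[ExpertCaseJudgment]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CASE_COLUMNS)
        for j in judgments:
            for factor, label in j.judgments.items():
                writer.writerow([j.case_id, j.expert_id, factor, label])


# ---------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------

def write_assessments_csv(
    path, assessments: list[CaseAssessment], scale: LinguisticScale
) -> None:
    """Assessment report: one row per case, one column per scale term."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["case_id", "mbd", "diagnosis"]
            + [f"degree_{lab}" for lab in scale.labels]
        )
        for a in assessments:
            writer.writerow(
                [a.case_id, repr(a.mbd), a.diagnosis]
                + [repr(a.fuzzified.get(lab, 0.0)) for lab in scale.labels]
            )


def write_validation_report(path, report: ValidationReport) -> None:
    """Structured validation summary (JSON) with the per-case table."""
    payload = {
        "n_cases": report.n_cases,
        "mean_difference": report.mean_difference,
        "t_statistic": report.t_statistic,
        "degrees_of_freedom": report.degrees_of_freedom,
        "p_value": report.p_value,
        "concordant": report.concordant,
        "label_agreement_rate": report.label_agreement_rate,
        "per_case": [
            {
                "case_id": c.case_id,
                "expert_score": c.expert_score,
                "model_score": c.model_score,
                "expert_label": c.expert_label,
                "model_label": c.model_label,
                "labels_agree": c.labels_agree,
            }
            for c in report.per_case
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, allow_nan=True), encoding="utf-8"
    )
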