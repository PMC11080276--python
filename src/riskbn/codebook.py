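"""Study codebook: variable definitions, categorical coding, discretization.

The case-control study records 27 variables per subject: 17 categorical
(demographics, family history, lifestyle, central obesity) and 10 continuous
(age, BMI, blood pressure, heart rate, and fasting labs).  Categorical
variables carry integer state codes with a designated reference (control)
level used for reference-coded logistic regression; continuous variables
carry clinical cut-points used to discretize them before network learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

GROUP_COLUMN = "group"
GROUPS = ("control", "T2DM", "CAD", "comorbidity")

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


class CodebookError(ValueError):
    """Raised for an inconsistent variable specification or config."""


class EncodingError(ValueError):
    """Raised when a raw value cannot be mapped to a declared state."""


@dataclass(frozen=True)
class VariableSpec:
    """One study variable: its kind, coding and (if continuous) bin rules.

    For categorical variables ``states`` maps label -> integer code and
    ``reference_code`` names the control level.  For continuous variables
    ``cutpoints`` are strictly increasing thresholds; ``bin_codes`` has one
    more entry than ``cutpoints`` and labels the half-open intervals
    ``(-inf, c0), [c0, c1), ..., [c_last, inf)`` so every real maps to
    exactly one bin.
    """

    name: str
    kind: str
    states: dict[str, int] | None = None
    reference_code: int | None = None
    cutpoints: tuple[float, ...] = ()
    bin_codes: tuple[int, ...] = ()
    units: str = ""
    skewed: bool = False  # summarized/tested nonparametrically (median, IQR)

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise CodebookError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if not self.states:
                raise CodebookError(f"{self.name}: categorical without states")
            codes = list(self.states.values())
            if len(set(codes)) != len(codes):
                raise CodebookError(f"{self.name}: duplicate state codes")
            if self.reference_code not in codes:
                raise CodebookError(
                    f"{self.name}: reference code {self.reference_code} "
                    f"not among state codes {codes}"
                )
        else:
            cuts = self.cutpoints
            if any(b >= a for a, b in zip(cuts[1:], cuts)):
                raise CodebookError(
                    f"{self.name}: cutpoints {cuts} not strictly increasing"
                )
            if len(self.bin_codes) != len(cuts) + 1:
                raise CodebookError(
                    f"{self.name}: need {len(cuts) + 1} bin codes, "
                    f"got {len(self.bin_codes)}"
                )

    @property
    def codes(self) -> tuple[int, ...]:
        """All legal integer codes for this variable (post-discretization)."""
        if self.kind == CATEGORICAL:
            return tuple(self.states.values())
        return tuple(sorted(set(self.bin_codes)))

    def encode_label(self, label) -> int:
        assert self.kind == CATEGORICAL
        if label in self.states:
            return self.states[label]
        # raw files may already hold integer codes
        try:
            code = int(label)
        except (TypeError, ValueError):
            raise EncodingError(
                f"{self.name}: unknown label {label!r}"
            ) from None
        if code not in self.states.values():
            raise EncodingError(f"{self.name}: unknown code {code}")
        return code

    def bin_value(self, x: float) -> int:
        """Map a numeric value to its bin code (total on the reals)."""
        assert self.kind == CONTINUOUS
        i = 0
        for cut in self.cutpoints:
            if x < cut:
                break
            i += 1
        return self.bin_codes[i]


@dataclass
class Codebook:
    """Ordered collection of variable specs plus outcome bookkeeping."""

    variables: dict[str, VariableSpec]
    outcome_names: tuple[str, ...] = ("T2DM", "CAD", "comorbidity")
    # per-outcome variables never analysed against that outcome
    exclusions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.variables)
        if len(set(names)) != len(names):
            raise CodebookError("duplicate variable names")

    def __getitem__(self, name: str) -> VariableSpec:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    @property
    def categorical(self) -> list[str]:
        return [n for n, v in self.variables.items() if v.kind == CATEGORICAL]

    @property
    def continuous(self) -> list[str]:
        return [n for n, v in self.variables.items() if v.kind == CONTINUOUS]

    def excluded_for(self, outcome: str) -> tuple[str, ...]:
        return self.exclusions.get(outcome, ())


def _cat(name, states, ref, units="") -> VariableSpec:
    return VariableSpec(
        name, CATEGORICAL, states=dict(states), reference_code=ref, units=units
    )


def _cont(name, cutpoints, bin_codes, units="", skewed=False) -> VariableSpec:
    return VariableSpec(
        name,
        CONTINUOUS,
        cutpoints=tuple(cutpoints),
        bin_codes=tuple(bin_codes),
        units=units,
        skewed=skewed,
    )


def default_codebook() -> Codebook:
    """The study's built-in codebook.

    Categorical codings follow the published assignment table (reference
    level = control level); continuous discretization follows the published
    clinical cut-point rules.  Heart rate is recorded as integer beats/min,
    so the "too fast (> 100)" bin opens at 101.  LDL-C is coded exactly as
    printed in the source table (normal = 0 for >= 1.0) even though the
    direction is clinically atypical; override via a custom config if needed.
    """
    variables = [
        _cont("age", [45, 60], [1, 2, 3], units="years"),
        _cat("sex", {"male": 1, "female": 2}, ref=1),
        _cat("area", {"rural": 1, "suburban": 2, "urban": 3}, ref=1),
        _cat("education", {"low": 1, "middle": 2, "high": 3}, ref=1),
        _cat("marriage", {"married": 1, "unmarried_divorced_widowed": 2}, ref=1),
        _cat(
            "occupation",
            {
                "agriculture_forestry": 1,
                "business_services": 2,
                "military_national_party": 3,
                "students": 4,
                "others": 5,
            },
            ref=1,
        ),
        _cat("fhx_dm", {"no": 0, "yes": 1}, ref=0),
        _cat("fhx_cad", {"no": 0, "yes": 1}, ref=0),
        _cat(
            "smoke",
            {"never": 1, "occasionally": 2, "often": 3, "quitting": 4},
            ref=1,
        ),
        _cat(
            "drink",
            {"never": 1, "occasionally": 2, "often": 3, "quitting": 4},
            ref=1,
        ),
        _cat(
            "staple_food",
            {"lt3": 1, "3_6": 2, "ge6": 3},
            ref=1,
            units="liang/day",
        ),
        _cat("meat", {"lt7": 1, "7_14": 2, "ge14": 3}, ref=1, units="times/week"),
        _cat(
            "vegetable",
            {"lt7": 1, "7_14": 2, "ge14": 3},
            ref=1,
            units="times/week",
        ),
        _cat(
            "fruit",
            {"never": 1, "lt7": 2, "7_14": 3, "ge14": 4},
            ref=1,
            units="times/week",
        ),
        _cat(
            "sweet",
            {"never": 1, "lt3": 2, "3_7": 3, "ge7": 4},
            ref=1,
            units="times/week",
        ),
        _cat("exercise", {"no": 0, "yes": 1}, ref=0),
        _cat(
            "sleep",
            {"lt5_or_medication": 1, "5_7": 2, "7_9": 3, "ge9": 4},
            ref=1,
            units="hours/day",
        ),
        _cont("bmi", [18.5, 24.0, 28.0], [1, 2, 3, 4], units="kg/m^2"),
        _cat("central_obesity", {"no": 0, "yes": 1}, ref=0),
        _cont("sbp", [140], [0, 1], units="mmHg"),
        _cont("dbp", [90], [0, 1], units="mmHg"),
        _cont("heart_rate", [60, 101], [1, 2, 3], units="times/min"),
        _cont("fbg", [7.0], [0, 1], units="mmol/L", skewed=True),
        _cont("tg", [2.3], [0, 1], units="mmol/L", skewed=True),
        _cont("tc", [6.2], [0, 1], units="mmol/L"),
        _cont("hdl_c", [2.3], [0, 1], units="mmol/L"),
        # printed rule: normal = 0 (>= 1.0), abnormal = 1 (< 1.0)
        _cont("ldl_c", [1.0], [1, 0], units="mmol/L"),
    ]
    return Codebook(
        variables={v.name: v for v in variables},
        # FBG is a diagnostic criterion for diabetes, so it is never analysed
        # against the diabetic outcomes.
        exclusions={"T2DM": ("fbg",)},
    )


def load_codebook(source) -> Codebook:
    """Build a Codebook from a YAML document (path, stream or dict).

    The document maps variable names to specs::

        age: {kind: continuous, cutpoints: [45, 60], bin_codes: [1, 2, 3]}
        sex: {kind: categorical, states: {male: 1, female: 2}, reference: male}

    ``exclusions`` (outcome -> variable list) is optional.  Validation errors
    raise :class:`CodebookError`.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise CodebookError("config must contain a 'variables' mapping")
    variables: dict[str, VariableSpec] = {}
    for name, spec in doc["variables"].items():
        if name in variables:
            raise CodebookError(f"duplicate variable {name!r}")
        kind = spec.get("kind")
        if kind == CATEGORICAL:
            states = dict(spec["states"])
            ref_label = spec.get("reference")
            if ref_label not in states:
                raise CodebookError(
                    f"{name}: reference level {ref_label!r} not among states"
                )
            variables[name] = _cat(
                name, states, ref=states[ref_label], units=spec.get("units", "")
            )
        else:
            variables[name] = _cont(
                name,
                spec.get("cutpoints", []),
                spec.get("bin_codes", []),
                units=spec.get("units", ""),
                skewed=bool(spec.get("skewed", False)),
            )
    exclusions = {
        k: tuple(v) for k, v in (doc.get("exclusions") or {}).items()
    }
    return Codebook(variables=variables, exclusions=exclusions)


def encode_dataset(raw: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Map categorical labels to their integer codes.

    Continuous columns pass through unchanged; the group column is validated
    against the study group labels.  Unknown labels raise
    :class:`EncodingError` naming the row and column.
    """
    if GROUP_COLUMN not in raw.columns:
        raise EncodingError(f"missing {GROUP_COLUMN!r} column")
    unknown = set(raw.columns) - set(codebook.variables) - {GROUP_COLUMN}
    if unknown:
        raise EncodingError(f"columns not in codebook: {sorted(unknown)}")
    bad_groups = set(raw[GROUP_COLUMN].unique()) - set(GROUPS)
    if bad_groups:
        raise EncodingError(f"unknown group labels: {sorted(bad_groups)}")
    out = raw.copy()
    for col in raw.columns:
        if col == GROUP_COLUMN:
            continue
        spec = codebook[col]
        if spec.kind != CATEGORICAL:
            out[col] = pd.to_numeric(raw[col])
            continue
        encoded = []
        for idx, label in raw[col].items():
            try:
                encoded.append(spec.encode_label(label))
            except EncodingError as err:
                raise EncodingError(f"row {idx}: {err}") from None
        out[col] = pd.Series(encoded, index=raw.index, dtype=int)
    return out


def discretize(table: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Replace every continuous column by its clinical bin code.

    Categorical columns and the group column are untouched, as is any
    column whose values already all lie in its bin-code set (raw clinical
    measurements can never do so), which makes the operation idempotent.
    Adult ages below 18 are accepted (they land in the lowest band) with a
    warning.
    """
    out = table.copy()
    for col in table.columns:
        if col == GROUP_COLUMN or codebook[col].kind != CONTINUOUS:
            continue
        spec = codebook[col]
        values = pd.to_numeric(table[col])
        if len(values) and set(values.unique()) <= set(spec.bin_codes):
            continue  # already discretized
        if col == "age" and (values < 18).any():
            warnings.warn(
                f"{int((values < 18).sum())} age value(s) below 18 assigned "
                "to the lowest age band",
                stacklevel=2,
            )
        out[col] = values.map(spec.bin_value).astype(int)
    return out
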