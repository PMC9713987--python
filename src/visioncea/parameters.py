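"""Domain types and parameter-file I/O for the visual-acuity Markov cost-utility model.

The model's health states are five visual-acuity (VA) bands in the
better-seeing eye (Snellen scale), ordered from best to worst, plus an
absorbing death state.  All monetary quantities are 2020 euros; all rates
and resource-use figures are per patient-year unless a field name says
otherwise.

Parameter files are human-readable YAML with explicit units in field names
(``*_eur_2020``, ``*_per_year``) so every number can be audited against its
source table.  Transition matrices may alternatively be supplied as CSV
tables with a header row of state labels; life tables are two-column CSV
(age, qx).
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "VAState",
    "STATE_LABELS",
    "N_VA_STATES",
    "DEATH_STATE",
    "ParameterValidationError",
    "MatrixValidationError",
    "ConfigurationError",
    "TransitionMatrix",
    "validate_matrix",
    "UtilityTable",
    "CostItem",
    "AdverseEvent",
    "ArmParameters",
    "LifeTable",
    "ModelConfig",
    "ParameterSet",
    "load_parameters",
    "write_parameters",
    "load_transition_csv",
    "write_transition_csv",
]

N_VA_STATES = 5
DEATH_STATE = 5

STATE_LABELS = (
    ">20/40",
    "<=20/40 to >20/80",
    "<=20/80 to >20/200",
    "<=20/200 to >20/400",
    "<=20/400",
    "death",
)


class VAState(enum.IntEnum):
    """Visual-acuity state in the better-seeing eye; index 0 is best vision.

    Ordering is fixed: indices 0-4 are VA bands of worsening acuity, index 5
    is the absorbing death state.
    """

    BETTER_THAN_20_40 = 0
    FROM_20_40_TO_20_80 = 1
    FROM_20_80_TO_20_200 = 2
    FROM_20_200_TO_20_400 = 3
    WORSE_THAN_20_400 = 4
    DEATH = 5

    @property
    def label(self) -> str:
        return STATE_LABELS[self.value]


class ParameterValidationError(ValueError):
    """A parameter file or object violates a structural invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class MatrixValidationError(ParameterValidationError):
    """A transition matrix fails row-stochasticity or structure checks."""


class ConfigurationError(ValueError):
    """A run configuration references unknown fields or invalid settings."""


# Allowed off-diagonal structure of the 5x5 per-cycle VA matrix: one-step
# improvement, plus one- and two-step worsening.  Entries outside this band
# are structurally zero.
_ALLOWED = np.zeros((N_VA_STATES, N_VA_STATES), dtype=bool)
for _i in range(N_VA_STATES):
    _ALLOWED[_i, _i] = True
    if _i >= 1:
        _ALLOWED[_i, _i - 1] = True
    if _i + 1 < N_VA_STATES:
        _ALLOWED[_i, _i + 1] = True
    if _i + 2 < N_VA_STATES:
        _ALLOWED[_i, _i + 2] = True

_ROW_SUM_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Per-cycle (3-month) transition probabilities among the 5 VA states.

    Pre-mortality: background death is embedded later, per cycle, from the
    life table.  Rows must be stochastic; nonzero entries are restricted to
    the diagonal, one-step improvement and the one/two-step worsening band.
    """

    entries: np.ndarray
    arm_label: str = ""

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (N_VA_STATES, N_VA_STATES):
            raise MatrixValidationError(
                f"transition[{self.arm_label}]",
                f"expected shape (5, 5), got {self.entries.shape}",
            )

    def validate(self) -> list[str]:
        return validate_matrix(self)

    def require_valid(self) -> "TransitionMatrix":
        violations = self.validate()
        if violations:
            raise MatrixValidationError(
                f"transition[{self.arm_label}]", "; ".join(violations)
            )
        return self


def validate_matrix(m: TransitionMatrix | np.ndarray) -> list[str]:
    """Return a list of violation messages; empty iff the matrix is valid.

    Checks: entries within [0, 1], each row sums to 1 within 1e-9, and no
    probability mass outside the allowed band structure.
    """
    entries = m.entries if isinstance(m, TransitionMatrix) else np.asarray(m, float)
    violations: list[str] = []
    if entries.shape != (N_VA_STATES, N_VA_STATES):
        return [f"expected shape (5, 5), got {entries.shape}"]
    for i in range(N_VA_STATES):
        row = entries[i]
        if np.any(row < 0) or np.any(row > 1):
            violations.append(f"row '{STATE_LABELS[i]}': entries outside [0, 1]")
        s = row.sum()
        if abs(s - 1.0) > _ROW_SUM_TOL:
            violations.append(f"row '{STATE_LABELS[i]}': sums to {s:.6g}, not 1")
        off_band = row[~_ALLOWED[i]]
        if np.any(off_band != 0):
            violations.append(
                f"row '{STATE_LABELS[i]}': nonzero entry outside allowed band"
            )
    return violations


@dataclass
class UtilityTable:
    """Per-VA-state utility weights under two elicitation methods.

    ``methods`` maps ``"TTO"`` / ``"SG"`` (time trade-off, standard gamble)
    to dicts with ``mean``, ``low``, ``high`` arrays of length 5.  The death
    state has utility exactly 0 and is not stored.  SG upper bounds may
    exceed 1 as published; samplers are responsible for clipping draws.
    """

    methods: dict[str, dict[str, np.ndarray]]

    def __post_init__(self):
        for meth, tbl in self.methods.items():
            for key in ("mean", "low", "high"):
                tbl[key] = np.asarray(tbl[key], dtype=float)
                if tbl[key].shape != (N_VA_STATES,):
                    raise ParameterValidationError(
                        f"utilities.{meth}.{key}", "expected 5 values"
                    )
            if np.any(tbl["mean"] < tbl["low"]) or np.any(tbl["mean"] > tbl["high"]):
                raise ParameterValidationError(
                    f"utilities.{meth}", "mean outside its printed range"
                )

    def utilities(self, method: str) -> np.ndarray:
        """Length-6 utility vector for the given method; death utility is 0."""
        if method not in self.methods:
            raise ConfigurationError(f"unknown utility method {method!r}")
        u = np.zeros(6)
        u[:N_VA_STATES] = self.methods[method]["mean"]
        return u

    def sampling_sd(self, method: str) -> np.ndarray:
        """SDs for PSA, derived from ranges as (high - low) / 4."""
        tbl = self.methods[method]
        return (tbl["high"] - tbl["low"]) / 4.0


@dataclass
class CostItem:
    """A priced follow-up resource (consultation or diagnostic procedure).

    ``unit_cost`` in 2020 euros with SD at a 20% variation coefficient;
    annual use has a mean and a (low, high) range for uniform PSA sampling.
    """

    name: str
    unit_cost: float
    unit_cost_sd: float
    annual_use_mean: float
    annual_use_low: float
    annual_use_high: float

    def __post_init__(self):
        if self.unit_cost <= 0:
            raise ParameterValidationError(f"cost_items.{self.name}.unit_cost",
                                           "must be positive")
        if not (self.annual_use_low <= self.annual_use_mean <= self.annual_use_high):
            raise ParameterValidationError(
                f"cost_items.{self.name}.annual_use",
                f"range ({self.annual_use_low}, {self.annual_use_high}) does not "
                f"bracket mean {self.annual_use_mean}",
            )

    @property
    def expected_annual_cost(self) -> float:
        return self.unit_cost * self.annual_use_mean


@dataclass
class AdverseEvent:
    """Adverse reaction priced as expected annual cost (rate x unit cost)."""

    name: str
    annual_rate: float
    unit_cost: float
    unit_cost_sd: float

    def __post_init__(self):
        if not 0 <= self.annual_rate <= 1:
            raise ParameterValidationError(f"adverse_events.{self.name}.annual_rate",
                                           "must be in [0, 1]")

    @property
    def expected_annual_cost(self) -> float:
        return self.annual_rate * self.unit_cost


@dataclass
class ArmParameters:
    """Everything specific to one treatment arm.

    ``other_annual_cost`` is the VA-independent annual cost for comorbidity
    care plus non-medical assistance; it is resolved from the shared cost
    block according to ``ModelConfig.other_cost_interpretation``.
    """

    name: str
    transition: TransitionMatrix
    drug_unit_cost: float
    drug_unit_cost_sd: float
    injections_per_year: float
    cost_items: list[CostItem]
    adverse_events: list[AdverseEvent]
    other_annual_cost: float
    rehab_annual_cost: float = 69.0
    equipment_annual_cost: float = 211.0

    def __post_init__(self):
        if self.injections_per_year <= 0:
            raise ParameterValidationError(f"arms.{self.name}.injections_per_year",
                                           "must be positive")
        self.transition.require_valid()

    def annual_treatment_cost(self) -> float:
        """Drug acquisition + monitoring + expected adverse-event cost, per year."""
        drug = self.drug_unit_cost * self.injections_per_year
        monitoring = sum(ci.expected_annual_cost for ci in self.cost_items)
        ae = sum(ev.expected_annual_cost for ev in self.adverse_events)
        return drug + monitoring + ae

    def annual_background_cost(self, include_indirect: bool = False,
                               indirect_annual_cost: float = 0.0) -> float:
        """Comorbidity/non-medical + rehabilitation + vision equipment, per year."""
        c = self.other_annual_cost + self.rehab_annual_cost + self.equipment_annual_cost
        if include_indirect:
            c += indirect_annual_cost
        return c


@dataclass
class LifeTable:
    """Annual probabilities of death q_x by integer age.

    Must cover every integer age from its first age through ``max_age``,
    where q is forced to 1.  Lookups clamp to the final row, so a cohort is
    always fully absorbed by ``max_age + 1``.
    """

    ages: np.ndarray
    qx: np.ndarray
    source: str = "unspecified"

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.shape != self.qx.shape or self.ages.ndim != 1:
            raise ParameterValidationError("life_table", "ages and qx must align")
        if np.any(np.diff(self.ages) != 1):
            raise ParameterValidationError("life_table", "ages must be consecutive")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ParameterValidationError("life_table", "qx outside [0, 1]")
        if self.qx[-1] != 1.0:
            raise ParameterValidationError("life_table", "final q must be exactly 1")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age_years: float) -> float:
        """q_x at floor(age); clamps to the terminal row (q = 1) beyond max_age."""
        a = int(np.floor(age_years))
        if a < self.min_age:
            raise ConfigurationError(
                f"age {age_years} below life-table range starting at {self.min_age}"
            )
        idx = min(a - self.min_age, len(self.qx) - 1)
        return float(self.qx[idx])

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise ParameterValidationError("life_table", f"{path}: need 2 columns")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   source=source or str(path))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("age,qx\n")
            for a, q in zip(self.ages, self.qx):
                fh.write(f"{int(a)},{float(q)!r}\n")


_DIST_PRESETS = {
    # Placeholder occupancy vectors over the 5 VA states; synthetic, for use
    # when no cohort-specific distribution is supplied.
    "synthetic_moderate": (0.10, 0.25, 0.30, 0.20, 0.15),
    "uniform": (0.2, 0.2, 0.2, 0.2, 0.2),
}


@dataclass
class ModelConfig:
    """Run configuration for the cohort model.

    ``horizon_years=None`` means a lifetime horizon (run to cohort
    absorption or the life-table terminal age).  ``extrapolation`` selects
    how year-1 trial effects are projected beyond the first year; see the
    scenarios module.  Discounting uses annual-equivalent compounding at
    cycle start times.
    """

    cycle_length_years: float = 0.25
    discount_rate_per_year: float = 0.035
    starting_age_years: float = 68.1
    horizon_years: float | None = None
    starting_distribution: np.ndarray = field(
        default_factory=lambda: np.array(_DIST_PRESETS["synthetic_moderate"]))
    starting_distribution_source: str = "synthetic_moderate"
    extrapolation: str = "continuous"
    utility_method: str = "TTO"
    half_cycle_correction: bool = False
    include_indirect_costs: bool = False
    indirect_annual_cost: float = 0.0
    other_cost_interpretation: str = "category"
    rebound_multiplier: float = 2.0
    rebound_tv_tolerance: float = 0.01
    seed: int = 1234

    _EXTRAPOLATIONS = ("continuous", "one_time_benefit", "rebound", "none")

    def __post_init__(self):
        if isinstance(self.starting_distribution, str):
            self.starting_distribution_source = self.starting_distribution
            try:
                self.starting_distribution = np.array(
                    _DIST_PRESETS[self.starting_distribution])
            except KeyError:
                raise ConfigurationError(
                    f"unknown starting-distribution preset "
                    f"{self.starting_distribution!r}") from None
        self.starting_distribution = np.asarray(self.starting_distribution, float)
        if self.starting_distribution.shape != (N_VA_STATES,):
            raise ParameterValidationError("starting_distribution",
                                           "expected 5 probabilities")
        if abs(self.starting_distribution.sum() - 1.0) > 1e-9:
            raise ParameterValidationError(
                "starting_distribution",
                f"sums to {self.starting_distribution.sum():.12g}, not 1")
        if np.any(self.starting_distribution < 0):
            raise ParameterValidationError("starting_distribution",
                                           "negative probability")
        if not 0 < self.cycle_length_years <= 1:
            raise ParameterValidationError("cycle_length_years", "must be in (0, 1]")
        if self.discount_rate_per_year < 0:
            raise ParameterValidationError("discount_rate_per_year",
                                           "must be nonnegative")
        if self.extrapolation not in self._EXTRAPOLATIONS:
            raise ConfigurationError(
                f"unknown extrapolation mode {self.extrapolation!r}; "
                f"choose one of {self._EXTRAPOLATIONS}")
        if self.utility_method not in ("TTO", "SG"):
            raise ConfigurationError(f"unknown utility method {self.utility_method!r}")
        if self.other_cost_interpretation not in ("category", "per_arm"):
            raise ConfigurationError(
                "other_cost_interpretation must be 'category' or 'per_arm'")

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ParameterSet:
    """A fully validated model input bundle: two arms, utilities, mortality, config."""

    arms: dict[str, ArmParameters]
    utilities: UtilityTable
    life: LifeTable
    config: ModelConfig
    reference_arm: str = "aflibercept"
    comparator_arm: str = "dexamethasone"
    other_costs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for role, name in (("reference", self.reference_arm),
                           ("comparator", self.comparator_arm)):
            if name not in self.arms:
                raise ConfigurationError(f"{role} arm {name!r} not among arms")

    @property
    def reference(self) -> ArmParameters:
        return self.arms[self.reference_arm]

    @property
    def comparator(self) -> ArmParameters:
        return self.arms[self.comparator_arm]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# YAML readers / writers
# ---------------------------------------------------------------------------

def _resolve_other_cost(other: dict[str, float], arm_name: str,
                        interpretation: str, ref_name: str) -> float:
    if interpretation == "category":
        # comorbidity + non-medical accrue to every patient regardless of arm
        return float(other["comorbidity_eur_2020_per_year"]
                     + other["non_medical_eur_2020_per_year"])
    # per-arm reading: first figure to the reference arm, second to the other
    vals = (other["comorbidity_eur_2020_per_year"],
            other["non_medical_eur_2020_per_year"])
    return float(vals[0] if arm_name == ref_name else vals[1])


def _build_armparams(name: str, doc: dict, config: ModelConfig,
                     ref_name: str) -> ArmParameters:
    raw = doc["transition_matrices"][name]
    tm = TransitionMatrix(np.array(raw, dtype=float), arm_label=name)
    violations = tm.validate()
    if violations:
        raise MatrixValidationError(f"transition_matrices.{name}",
                                    "; ".join(violations))
    drug = doc["drugs"][name]
    items = []
    for item_name, item in sorted(doc["cost_items"].items()):
        use = item["annual_use_per_year"][name]
        items.append(CostItem(
            name=item_name,
            unit_cost=float(item["unit_cost_eur_2020"]),
            unit_cost_sd=float(item["unit_cost_sd_eur"]),
            annual_use_mean=float(use["mean"]),
            annual_use_low=float(use["low"]),
            annual_use_high=float(use["high"]),
        ))
    events = []
    for ev_name, ev in sorted(doc["adverse_events"].items()):
        events.append(AdverseEvent(
            name=ev_name,
            annual_rate=float(ev["annual_rate_per_year"][name]),
            unit_cost=float(ev["unit_cost_eur_2020"]),
            unit_cost_sd=float(ev["unit_cost_sd_eur"]),
        ))
    other = _resolve_other_cost(doc["other_annual_costs"], name,
                                config.other_cost_interpretation, ref_name)
    extra = doc.get("care_costs", {})
    return ArmParameters(
        name=name,
        transition=tm,
        drug_unit_cost=float(drug["vial_cost_eur_2020"]),
        drug_unit_cost_sd=float(drug["vial_cost_sd_eur"]),
        injections_per_year=float(drug["injections_per_year"]),
        cost_items=items,
        adverse_events=events,
        other_annual_cost=other,
        rehab_annual_cost=float(
            extra.get("vision_rehabilitation_eur_2020_per_year", 69.0)),
        equipment_annual_cost=float(
            extra.get("vision_enhancing_equipment_eur_2020_per_year", 211.0)),
    )


def _build_config(doc: dict) -> ModelConfig:
    model = dict(doc.get("model", {}))
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(model) - known
    if unknown:
        raise ConfigurationError(f"unknown model config fields: {sorted(unknown)}")
    return ModelConfig(**model)


def _build_life(doc: dict, base_dir: Path) -> LifeTable:
    from . import synthetic

    spec = doc.get("life_table", {"type": "synthetic_gompertz"})
    kind = spec.get("type", "synthetic_gompertz")
    if kind == "csv":
        return LifeTable.from_csv(base_dir / spec["path"])
    if kind == "synthetic_gompertz":
        g = synthetic.GompertzSpec(
            a=float(spec.get("a_per_year", synthetic.DEFAULT_GOMPERTZ.a)),
            b=float(spec.get("b_per_year_of_age", synthetic.DEFAULT_GOMPERTZ.b)),
            c=float(spec.get("c_per_year", synthetic.DEFAULT_GOMPERTZ.c)),
            start_age=int(spec.get("start_age", synthetic.DEFAULT_GOMPERTZ.start_age)),
            max_age=int(spec.get("max_age", synthetic.DEFAULT_GOMPERTZ.max_age)),
        )
        return synthetic.make_life_table(g)
    raise ConfigurationError(f"unknown life_table type {kind!r}")


def load_parameters(path: str | Path,
                    life_table: LifeTable | None = None) -> ParameterSet:
    """Load and validate a full parameter set from a YAML file.

    ``life_table`` overrides whatever the file specifies (use it to supply a
    real national life table as a two-column CSV read via
    :meth:`LifeTable.from_csv`).

    Raises :class:`ParameterValidationError` (naming the offending field) or
    :class:`MatrixValidationError` (naming the offending row) on invalid input.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    config = _build_config(doc)

    util_doc = doc["utilities"]
    methods = {}
    for meth in ("TTO", "SG"):
        rows = util_doc[meth]
        methods[meth] = {
            "mean": np.array([r["mean"] for r in rows], float),
            "low": np.array([r["low"] for r in rows], float),
            "high": np.array([r["high"] for r in rows], float),
        }
    utilities = UtilityTable(methods)

    ref_name = doc.get("reference_arm", "aflibercept")
    cmp_name = doc.get("comparator_arm", "dexamethasone")
    arms = {name: _build_armparams(name, doc, config, ref_name)
            for name in doc["transition_matrices"]}

    life = life_table if life_table is not None else _build_life(doc, path.parent)

    return ParameterSet(
        arms=arms, utilities=utilities, life=life, config=config,
        reference_arm=ref_name, comparator_arm=cmp_name,
        other_costs={k: float(v) for k, v in doc["other_annual_costs"].items()},
    )


def _config_to_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["starting_distribution"] = [float(x) for x in config.starting_distribution]
    return d


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Serialise a parameter set back to YAML (sorted keys, stable formatting).

    Round-trips through :func:`load_parameters` reproduce every numeric field
    exactly (floats are emitted at full precision).
    """
    any_arm = next(iter(ps.arms.values()))
    doc: dict = {
        "reference_arm": ps.reference_arm,
        "comparator_arm": ps.comparator_arm,
        "model": _config_to_dict(ps.config),
        "life_table": {
            "type": "csv_inline_unsupported"  # replaced below
        },
        "transition_matrices": {
            name: [[float(x) for x in row] for row in arm.transition.entries]
            for name, arm in ps.arms.items()
        },
        "utilities": {
            meth: [
                {"mean": float(tbl["mean"][i]), "low": float(tbl["low"][i]),
                 "high": float(tbl["high"][i])}
                for i in range(N_VA_STATES)
            ]
            for meth, tbl in ps.utilities.methods.items()
        },
        "drugs": {
            name: {
                "vial_cost_eur_2020": float(arm.drug_unit_cost),
                "vial_cost_sd_eur": float(arm.drug_unit_cost_sd),
                "injections_per_year": float(arm.injections_per_year),
            }
            for name, arm in ps.arms.items()
        },
        "cost_items": {},
        "adverse_events": {},
        "other_annual_costs": {k: float(v) for k, v in ps.other_costs.items()},
        "care_costs": {
            "vision_rehabilitation_eur_2020_per_year": float(any_arm.rehab_annual_cost),
            "vision_enhancing_equipment_eur_2020_per_year":
                float(any_arm.equipment_annual_cost),
        },
    }
    # life table written alongside as CSV
    life_csv = Path(path).with_suffix(".life.csv")
    ps.life.to_csv(life_csv)
    doc["life_table"] = {"type": "csv", "path": life_csv.name}

    for name, arm in ps.arms.items():
        for ci in arm.cost_items:
            entry = doc["cost_items"].setdefault(ci.name, {
                "unit_cost_eur_2020": float(ci.unit_cost),
                "unit_cost_sd_eur": float(ci.unit_cost_sd),
                "annual_use_per_year": {},
            })
            entry["annual_use_per_year"][name] = {
                "mean": float(ci.annual_use_mean),
                "low": float(ci.annual_use_low),
                "high": float(ci.annual_use_high),
            }
        for ev in arm.adverse_events:
            entry = doc["adverse_events"].setdefault(ev.name, {
                "unit_cost_eur_2020": float(ev.unit_cost),
                "unit_cost_sd_eur": float(ev.unit_cost_sd),
                "annual_rate_per_year": {},
            })
            entry["annual_rate_per_year"][name] = float(ev.annual_rate)

    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=True, default_flow_style=False,
                   allow_unicode=True)
    Path(path).write_text(buf.getvalue())


def load_transition_csv(path: str | Path, arm_label: str = "") -> TransitionMatrix:
    """Read a 5x5 transition matrix from CSV with a header row of state labels."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return TransitionMatrix(df.to_numpy(dtype=float), arm_label=arm_label)


def write_transition_csv(tm: TransitionMatrix, path: str | Path) -> None:
    labels = STATE_LABELS[:N_VA_STATES]
    with open(path, "w") as fh:
        fh.write("state," + ",".join(labels) + "\n")
        for i, row in enumerate(tm.entries):
            fh.write(labels[i] + "," + ",".join(repr(float(x)) for x in row) + "\n")


def reference_parameter_path() -> Path:
    """Path to the bundled parameter file transcribing the published inputs."""
    return Path(__file__).parent / "data" / "reference_parameters.yaml"


def load_reference_parameters(life_table: LifeTable | None = None) -> ParameterSet:
    """Load the bundled published inputs (see ``data/reference_parameters.yaml``).

    The bundled file carries the published transition matrices, utilities and
    unit costs, but the life table and starting VA distribution are synthetic
    stand-ins unless overridden.
    """
    return load_parameters(reference_parameter_path(), life_table=life_table)
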