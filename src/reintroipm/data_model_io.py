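"""Domain types, validation and readers/writers for mark-resighting datasets.

A dataset bundles four tables: individual covariates, a binary detection
matrix over annual survey occasions, per-female annual fledgling counts with
a density covariate, and per-survey counts of unbanded birds.  Two on-disk
dialects are supported: a directory of CSV files (``csv-bundle``) and the
classic S-PLUS/R dump used by BUGS (``bugs-dump``).

Occasion indexing is 0-based throughout.  Occasion 0 is the release event;
occasions 1..T-1 are the September surveys.  The interval between release
and the first survey may be a fraction of a year (``first_interval_fraction``,
0.5 for the case study).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEX_CODES = {"M": "male", "F": "female", "U": "unknown"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}

__all__ = [
    "Individual",
    "CaptureHistory",
    "FecundityRecord",
    "UnbandedCount",
    "ParameterSet",
    "ModelConfig",
    "Dataset",
    "ValidationError",
    "BugsParseError",
    "read_dataset",
    "write_dataset",
    "write_bugs_dump",
    "parse_bugs_dump",
]


class ValidationError(ValueError):
    """A dataset violated a structural invariant."""


class BugsParseError(ValueError):
    """Malformed BUGS dump syntax; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Individual:
    """One marked bird.

    ``first_occasion`` is the 0-based survey index of first capture or
    release.  ``banding_method`` is only meaningful for wild-born birds;
    for translocated founders it is recorded as ``not-applicable``.
    """

    id: str
    sex: str  # "male" | "female" | "unknown"
    origin: str  # "translocated" | "wild-born"
    banding_method: str  # "nestling" | "fledgling" | "not-applicable"
    first_occasion: int

    def __post_init__(self):
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"individual {self.id!r}: unknown sex code {self.sex!r}")
        if self.origin not in ("translocated", "wild-born"):
            raise ValidationError(f"individual {self.id!r}: unknown origin {self.origin!r}")
        if self.origin == "translocated":
            object.__setattr__(self, "banding_method", "not-applicable")
        elif self.banding_method not in ("nestling", "fledgling"):
            raise ValidationError(
                f"individual {self.id!r}: unknown banding method {self.banding_method!r}"
            )
        if self.first_occasion < 0:
            raise ValidationError(f"individual {self.id!r}: negative first_occasion")


@dataclass
class CaptureHistory:
    """Detection matrix (individual x occasion) plus the individual registry."""

    individuals: list[Individual]
    detections: np.ndarray  # (n, T) of {0,1}
    occasions: list[str]
    first_interval_fraction: float = 1.0

    def __post_init__(self):
        self.detections = np.asarray(self.detections, dtype=np.int8)
        self.validate()

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def first_occasions(self) -> np.ndarray:
        return np.array([ind.first_occasion for ind in self.individuals], dtype=int)

    def validate(self) -> None:
        n, T = self.detections.shape
        if n != len(self.individuals):
            raise ValidationError(
                f"detection matrix has {n} rows for {len(self.individuals)} individuals"
            )
        if T != len(self.occasions):
            raise ValidationError(
                f"detection matrix has {T} columns for {len(self.occasions)} occasions"
            )
        if not np.isin(self.detections, (0, 1)).all():
            raise ValidationError("detection matrix entries must be 0 or 1")
        if not 0.0 < self.first_interval_fraction <= 1.0:
            raise ValidationError("first_interval_fraction must be in (0, 1]")
        seen = set()
        for i, ind in enumerate(self.individuals):
            if ind.id in seen:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
            if ind.first_occasion >= T:
                raise ValidationError(
                    f"individual {ind.id!r}: first_occasion {ind.first_occasion} "
                    f"outside occasion range 0..{T - 1}"
                )
            if self.detections[i, ind.first_occasion] != 1:
                raise ValidationError(
                    f"individual {ind.id!r}: not detected at its first occasion"
                )
            if self.detections[i, : ind.first_occasion].any():
                raise ValidationError(
                    f"individual {ind.id!r}: detection before first occasion "
                    f"{ind.first_occasion}"
                )

    def truncate(self, n_occasions: int) -> "CaptureHistory":
        """Keep only the first ``n_occasions`` survey columns (and the
        individuals first seen within them)."""
        if not 1 <= n_occasions <= self.n_occasions:
            raise ValueError("n_occasions out of range")
        keep = [i for i, ind in enumerate(self.individuals) if ind.first_occasion < n_occasions]
        return CaptureHistory(
            individuals=[self.individuals[i] for i in keep],
            detections=self.detections[keep, :n_occasions].copy(),
            occasions=list(self.occasions[:n_occasions]),
            first_interval_fraction=self.first_interval_fraction,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CaptureHistory)
            and self.individuals == other.individuals
            and np.array_equal(self.detections, other.detections)
            and self.occasions == other.occasions
            and self.first_interval_fraction == other.first_interval_fraction
        )


@dataclass(frozen=True)
class FecundityRecord:
    """Fledglings produced by one female in one breeding season.

    ``density`` is the breeding population size at the start of that season.
    """

    female_id: str
    year: int  # survey occasion index at the start of the season
    fledglings: int
    density: float

    def __post_init__(self):
        if self.fledglings < 0:
            raise ValidationError(f"female {self.female_id!r}: negative fledgling count")
        if self.density <= 0:
            raise ValidationError(f"female {self.female_id!r}: density must be > 0")


@dataclass(frozen=True)
class UnbandedCount:
    """Number of unbanded birds seen at one survey, by sex."""

    occasion: int
    sex: str
    count: int

    def __post_init__(self):
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"unbanded count: unknown sex code {self.sex!r}")
        if self.count < 0:
            raise ValidationError("unbanded count must be >= 0")


@dataclass
class ParameterSet:
    """One realization of every demographic parameter.

    Survival probabilities are annual; regression coefficients live on the
    link scale (logit for survival and resighting, log for fecundity).
    Density slopes are per bird on the raw density scale.
    """

    phi_a: float = 0.78  # annual adult survival
    phi_j_mean: float = 0.25  # mean-year juvenile survival (fledging -> adulthood)
    sigma_year_j: float = 0.0  # SD of year effect on logit juvenile survival
    eps_year_j: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_dens_j: float = 0.0  # density slope on logit juvenile survival (per bird)
    gamma_band: float = 0.0  # fledgling-banded vs nestling-banded effect
    beta_sex: float = 0.0  # male vs female effect on logit adult survival
    delta_trans: float = 0.0  # founders' first-interval effect
    p: float = 0.9  # per-survey resighting probability
    sigma_year_p: float = 0.0
    eps_year_p: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha_f: float = float(np.log(3.8))  # log mean fecundity at density 0
    beta_dens_f: float = 0.0  # density slope on log fecundity (per bird)
    sigma_female: float = 0.0
    eps_female: dict = field(default_factory=dict)  # female id -> deviate
    sigma_year_f: float = 0.0
    eps_year_f: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.eps_year_j = np.asarray(self.eps_year_j, dtype=float)
        self.eps_year_p = np.asarray(self.eps_year_p, dtype=float)
        self.eps_year_f = np.asarray(self.eps_year_f, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("phi_a", "phi_j_mean", "p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} not in (0, 1)")
        for name in ("sigma_year_j", "sigma_year_p", "sigma_female", "sigma_year_f"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def mean_fecundity(self, density: float = 0.0) -> float:
        """Average-female, average-year fledglings per female (random effects 0)."""
        return float(np.exp(self.alpha_f + self.beta_dens_f * density))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("eps_year_j", "eps_year_p", "eps_year_f"):
            d[key] = [float(x) for x in d[key]]
        d["eps_female"] = {k: float(v) for k, v in d["eps_female"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)


#: flags of the full model, in the order used by ``ModelConfig``
_EFFECT_FLAGS = (
    "density_on_fecundity",
    "year_re_on_fecundity",
    "female_re_on_fecundity",
    "density_on_juvenile",
    "sex_on_adult",
    "translocation_effect",
    "banding_age_effect",
    "year_re_on_juvenile",
    "year_re_on_resighting",
)


@dataclass
class ModelConfig:
    """Which optional effects are in the model, plus sampler settings.

    The defaults reproduce the full model: every optional effect enabled.
    """

    density_on_fecundity: bool = True
    year_re_on_fecundity: bool = True
    female_re_on_fecundity: bool = True
    density_on_juvenile: bool = True
    sex_on_adult: bool = True
    translocation_effect: bool = True
    banding_age_effect: bool = True
    year_re_on_juvenile: bool = True
    year_re_on_resighting: bool = True
    prior_mode: str = "uninformative"  # or "informative"
    iterations: int = 12000
    burn_in: int = 4000
    chains: int = 2
    thin: int = 2
    seed: int = 20070301
    check_convergence: bool = True
    rhat_threshold: float = 1.1
    sd_drop_quantile: float = 0.25  # random-effect reduction rule
    sd_drop_threshold: float = 0.05

    def __post_init__(self):
        if self.prior_mode not in ("informative", "uninformative"):
            raise ValidationError(f"unknown prior_mode {self.prior_mode!r}")
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.chains < 1 or self.thin < 1:
            raise ValidationError("chains and thin must be >= 1")

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """The reduced model kept after backwards elimination: constant adult
        survival and resighting, year random effect on juvenile survival,
        female random effect on fecundity."""
        base = dict(
            density_on_fecundity=False,
            year_re_on_fecundity=False,
            female_re_on_fecundity=True,
            density_on_juvenile=False,
            sex_on_adult=False,
            translocation_effect=False,
            banding_age_effect=False,
            year_re_on_juvenile=True,
            year_re_on_resighting=False,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "ModelConfig":
        return dataclasses.replace(self, **overrides)

    def enabled_effects(self) -> list[str]:
        return [f for f in _EFFECT_FLAGS if getattr(self, f)]


@dataclass
class Dataset:
    """A full analysis input: capture history + fecundity + unbanded counts."""

    history: CaptureHistory
    fecundity: list[FecundityRecord]
    unbanded: list[UnbandedCount]
    extinct: bool = False  # set by the simulator when the population died out

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = {ind.id for ind in self.history.individuals}
        females = {ind.id for ind in self.history.individuals if ind.sex == "female"}
        T = self.history.n_occasions
        for rec in self.fecundity:
            if rec.female_id not in ids:
                raise ValidationError(
                    f"fecundity record references unknown female {rec.female_id!r}"
                )
            if rec.female_id not in females:
                raise ValidationError(
                    f"fecundity record references non-female individual {rec.female_id!r}"
                )
            if not 0 <= rec.year < T:
                raise ValidationError(
                    f"fecundity record year {rec.year} outside occasion range"
                )
        for uc in self.unbanded:
            if not 0 <= uc.occasion < T:
                raise ValidationError(
                    f"unbanded count occasion {uc.occasion} outside occasion range"
                )

    def truncate(self, n_occasions: int) -> "Dataset":
        """Restrict to the first ``n_occasions`` occasions: detections through
        occasion ``n_occasions - 1``, fecundity seasons starting at a kept
        survey (year < n_occasions), unbanded counts at kept occasions.
        Truncating at the full length is the identity."""
        hist = self.history.truncate(n_occasions)
        fec = [r for r in self.fecundity if r.year < n_occasions]
        unb = [u for u in self.unbanded if u.occasion < n_occasions]
        return Dataset(history=hist, fecundity=fec, unbanded=unb, extinct=self.extinct)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dataset)
            and self.history == other.history
            and self.fecundity == other.fecundity
            and self.unbanded == other.unbanded
        )


# ---------------------------------------------------------------------------
# csv-bundle IO
# ---------------------------------------------------------------------------

def _occ_cols(T: int) -> list[str]:
    return [f"occ_{t}" for t in range(T)]


def write_dataset(data: Dataset, path: str | Path) -> Path:
    """Write a dataset as a csv-bundle directory (lossless round trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    hist = data.history
    pd.DataFrame(
        {
            "id": [i.id for i in hist.individuals],
            "sex": [SEX_TO_CODE[i.sex] for i in hist.individuals],
            "origin": [i.origin for i in hist.individuals],
            "banding_method": [i.banding_method for i in hist.individuals],
            "first_occasion": [i.first_occasion for i in hist.individuals],
        }
    ).to_csv(path / "individuals.csv", index=False)
    det = pd.DataFrame(hist.detections, columns=_occ_cols(hist.n_occasions))
    det.insert(0, "id", [i.id for i in hist.individuals])
    det.to_csv(path / "detections.csv", index=False)
    pd.DataFrame(
        {
            "female_id": [r.female_id for r in data.fecundity],
            "year": [r.year for r in data.fecundity],
            "fledglings": [r.fledglings for r in data.fecundity],
            "density": [r.density for r in data.fecundity],
        }
    ).to_csv(path / "fecundity.csv", index=False)
    pd.DataFrame(
        {
            "occasion": [u.occasion for u in data.unbanded],
            "sex": [SEX_TO_CODE[u.sex] for u in data.unbanded],
            "count": [u.count for u in data.unbanded],
        }
    ).to_csv(path / "unbanded.csv", index=False)
    pd.DataFrame(
        {
            "index": range(hist.n_occasions),
            "label": hist.occasions,
            "first_interval_fraction": [hist.first_interval_fraction]
            + [""] * (hist.n_occasions - 1),
        }
    ).to_csv(path / "occasions.csv", index=False)
    return path


def _read_csv_bundle(path: Path) -> Dataset:
    for name in ("individuals", "detections", "fecundity", "unbanded", "occasions"):
        if not (path / f"{name}.csv").exists():
            raise FileNotFoundError(f"csv-bundle is missing {name}.csv in {path}")
    ind_df = pd.read_csv(path / "individuals.csv", dtype={"id": str})
    det_df = pd.read_csv(path / "detections.csv", dtype={"id": str})
    fec_df = pd.read_csv(path / "fecundity.csv", dtype={"female_id": str})
    unb_df = pd.read_csv(path / "unbanded.csv")
    occ_df = pd.read_csv(path / "occasions.csv")

    individuals = []
    for row in ind_df.itertuples(index=False):
        code = str(row.sex).strip().upper()
        if code not in SEX_CODES:
            raise ValidationError(f"individual {row.id!r}: unknown sex code {row.sex!r}")
        individuals.append(
            Individual(
                id=str(row.id),
                sex=SEX_CODES[code],
                origin=str(row.origin),
                banding_method=str(row.banding_method),
                first_occasion=int(row.first_occasion),
            )
        )
    det_df = det_df.set_index("id").loc[[i.id for i in individuals]]
    occ_labels = [str(x) for x in occ_df["label"].tolist()]
    frac_col = occ_df["first_interval_fraction"].tolist() if "first_interval_fraction" in occ_df else [1.0]
    try:
        frac = float(frac_col[0])
    except (TypeError, ValueError):
        frac = 1.0
    history = CaptureHistory(
        individuals=individuals,
        detections=det_df[_occ_cols(len(occ_labels))].to_numpy(dtype=np.int8),
        occasions=occ_labels,
        first_interval_fraction=frac,
    )
    fecundity = [
        FecundityRecord(
            female_id=str(r.female_id),
            year=int(r.year),
            fledglings=int(r.fledglings),
            density=float(r.density),
        )
        for r in fec_df.itertuples(index=False)
    ]
    unbanded = []
    for r in unb_df.itertuples(index=False):
        code = str(r.sex).strip().upper()
        if code not in SEX_CODES:
            raise ValidationError(f"unbanded counts: unknown sex code {r.sex!r}")
        unbanded.append(
            UnbandedCount(occasion=int(r.occasion), sex=SEX_CODES[code], count=int(r.count))
        )
    return Dataset(history=history, fecundity=fecundity, unbanded=unbanded)


# ---------------------------------------------------------------------------
# BUGS dump parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<name>[A-Za-z.][A-Za-z0-9._]*)
      | (?P<number>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)
      | (?P<punct>[(),=])
      | (?P<string>"[^"]*")
    )""",
    re.VERBOSE,
)


def _tokenize_bugs(text: str):
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0]
        pos = 0
        while pos < len(body):
            if body[pos].isspace():
                pos += 1
                continue
            m = _TOKEN_RE.match(body, pos)
            if m is None or m.end() == pos:
                raise BugsParseError(f"unexpected character {body[pos]!r}", lineno)
            tokens.append((m, lineno))
            pos = m.end()
    return tokens


class _BugsParser:
    """Recursive-descent parser for the R-dump subset
    ``list(name=value, name=c(...), name=structure(.Data=c(...), .Dim=c(...)))``."""

    def __init__(self, text: str):
        self.tokens = _tokenize_bugs(text)
        self.pos = 0

    def _peek(self):
        if self.pos >= len(self.tokens):
            raise BugsParseError("unexpected end of input", self.tokens[-1][1] if self.tokens else 1)
        return self.tokens[self.pos]

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _expect_punct(self, ch: str):
        m, lineno = self._next()
        if m.lastgroup != "punct" or m.group() .strip() != ch:
            raise BugsParseError(f"expected {ch!r}, got {m.group().strip()!r}", lineno)

    def _expect_name(self, name: str | None = None) -> str:
        m, lineno = self._next()
        if m.lastgroup != "name":
            raise BugsParseError(f"expected a name, got {m.group().strip()!r}", lineno)
        got = m.group().strip()
        if name is not None and got != name:
            raise BugsParseError(f"expected {name!r}, got {got!r}", lineno)
        return got

    def parse(self) -> dict:
        self._expect_name("list")
        self._expect_punct("(")
        out: dict[str, object] = {}
        while True:
            key = self._expect_name()
            self._expect_punct("=")
            out[key] = self._value()
            m, lineno = self._next()
            tok = m.group().strip()
            if tok == ")":
                break
            if tok != ",":
                raise BugsParseError(f"expected ',' or ')', got {tok!r}", lineno)
        if self.pos != len(self.tokens):
            _, lineno = self.tokens[self.pos]
            raise BugsParseError("trailing content after list(...)", lineno)
        return out

    def _value(self):
        m, lineno = self._peek()
        if m.lastgroup == "number":
            self.pos += 1
            return float(m.group())
        if m.lastgroup == "string":
            self.pos += 1
            return m.group().strip()[1:-1]
        if m.lastgroup == "name":
            name = m.group().strip()
            if name == "c":
                return self._vector()
            if name == "structure":
                return self._structure()
            if name == "NA":
                self.pos += 1
                return float("nan")
            raise BugsParseError(f"unsupported construct {name!r}", lineno)
        raise BugsParseError(f"unexpected token {m.group().strip()!r}", lineno)

    def _vector(self) -> np.ndarray:
        self._expect_name("c")
        self._expect_punct("(")
        values = []
        while True:
            m, lineno = self._next()
            if m.lastgroup == "number":
                values.append(float(m.group()))
            elif m.lastgroup == "name" and m.group().strip() == "NA":
                values.append(float("nan"))
            else:
                raise BugsParseError(
                    f"expected a number in c(...), got {m.group().strip()!r}", lineno
                )
            m, lineno = self._next()
            tok = m.group().strip()
            if tok == ")":
                break
            if tok != ",":
                raise BugsParseError(f"expected ',' or ')' in c(...), got {tok!r}", lineno)
        return np.array(values)

    def _structure(self) -> np.ndarray:
        self._expect_name("structure")
        self._expect_punct("(")
        self._expect_name(".Data")
        self._expect_punct("=")
        data = self._vector()
        self._expect_punct(",")
        self._expect_name(".Dim")
        self._expect_punct("=")
        dim = self._vector()
        self._expect_punct(")")
        # R stores .Data in row-major order for BUGS dumps
        return data.reshape(tuple(int(d) for d in dim))


def parse_bugs_dump(text: str) -> dict:
    """Parse the ``list(...)`` subset of the S-PLUS/R dump dialect into a dict
    of scalars and numpy arrays."""
    return _BugsParser(text).parse()


_BUGS_SEX = {1.0: "male", 2.0: "female", 3.0: "unknown"}


def _read_bugs_dump(path: Path) -> Dataset:
    """Canonical variable layout for the bugs-dump dialect:

    ``y`` (n x T detection matrix), ``first`` (1-based first occasions),
    ``sex`` (1=male, 2=female, 3=unknown), ``trans`` (1 if translocated),
    ``band_fl`` (1 if banded as fledgling), ``frac1`` (first interval
    fraction), and optionally ``fec_female`` (1-based row index into the
    individuals), ``fec_year`` (1-based occasion), ``fec_count``,
    ``fec_density``, ``unb_occ``, ``unb_sex``, ``unb_count``.
    """
    vars_ = parse_bugs_dump(path.read_text())
    for required in ("y", "first", "sex"):
        if required not in vars_:
            raise ValidationError(f"bugs-dump is missing variable {required!r}")
    y = np.asarray(vars_["y"])
    if y.ndim != 2:
        raise ValidationError("bugs-dump variable 'y' must be a matrix")
    y = np.nan_to_num(y, nan=0.0)
    n, T = y.shape
    first = np.asarray(vars_["first"], dtype=float).astype(int) - 1
    sex = np.asarray(vars_["sex"], dtype=float)
    trans = np.asarray(vars_.get("trans", np.zeros(n)), dtype=float)
    band_fl = np.asarray(vars_.get("band_fl", np.zeros(n)), dtype=float)
    frac = float(np.atleast_1d(vars_.get("frac1", 1.0))[0])
    individuals = []
    for i in range(n):
        if sex[i] not in _BUGS_SEX:
            raise ValidationError(f"individual ind_{i + 1}: unknown sex code {sex[i]!r}")
        individuals.append(
            Individual(
                id=f"ind_{i + 1}",
                sex=_BUGS_SEX[sex[i]],
                origin="translocated" if trans[i] == 1 else "wild-born",
                banding_method="not-applicable"
                if trans[i] == 1
                else ("fledgling" if band_fl[i] == 1 else "nestling"),
                first_occasion=int(first[i]),
            )
        )
    history = CaptureHistory(
        individuals=individuals,
        detections=y.astype(np.int8),
        occasions=[f"occ_{t}" for t in range(T)],
        first_interval_fraction=frac,
    )
    fecundity = []
    if "fec_female" in vars_:
        fem = np.asarray(vars_["fec_female"], dtype=float).astype(int) - 1
        yr = np.asarray(vars_["fec_year"], dtype=float).astype(int) - 1
        cnt = np.asarray(vars_["fec_count"], dtype=float).astype(int)
        dens = np.asarray(vars_["fec_density"], dtype=float)
        for k in range(len(fem)):
            fecundity.append(
                FecundityRecord(
                    female_id=individuals[fem[k]].id,
                    year=int(yr[k]),
                    fledglings=int(cnt[k]),
                    density=float(dens[k]),
                )
            )
    unbanded = []
    if "unb_occ" in vars_:
        occ = np.asarray(vars_["unb_occ"], dtype=float).astype(int) - 1
        usex = np.asarray(vars_["unb_sex"], dtype=float)
        ucnt = np.asarray(vars_["unb_count"], dtype=float).astype(int)
        for k in range(len(occ)):
            unbanded.append(
                UnbandedCount(occasion=int(occ[k]), sex=_BUGS_SEX[usex[k]], count=int(ucnt[k]))
            )
    return Dataset(history=history, fecundity=fecundity, unbanded=unbanded)


def write_bugs_dump(data: Dataset, path: str | Path) -> Path:
    """Write a dataset as a single BUGS-dialect dump file using the canonical
    variable layout of :func:`_read_bugs_dump`.  Individual ids are positional
    (``ind_<row>``), so a round trip preserves structure, not id strings."""
    path = Path(path)
    hist = data.history
    n, T = hist.detections.shape
    sex_code = {"male": 1, "female": 2, "unknown": 3}
    id_to_row = {ind.id: i + 1 for i, ind in enumerate(hist.individuals)}

    def vec(values, fmt="{:g}"):
        return "c(" + ",".join(fmt.format(v) for v in values) + ")"

    parts = [
        "list(",
        f"y=structure(.Data={vec(hist.detections.reshape(-1))}, .Dim=c({n},{T})),",
        f"first={vec(hist.first_occasions + 1)},",
        f"sex={vec([sex_code[i.sex] for i in hist.individuals])},",
        f"trans={vec([1 if i.origin == 'translocated' else 0 for i in hist.individuals])},",
        f"band_fl={vec([1 if i.banding_method == 'fledgling' else 0 for i in hist.individuals])},",
        f"frac1={hist.first_interval_fraction:g}",
    ]
    if data.fecundity:
        parts[-1] += ","
        parts += [
            f"fec_female={vec([id_to_row[r.female_id] for r in data.fecundity])},",
            f"fec_year={vec([r.year + 1 for r in data.fecundity])},",
            f"fec_count={vec([r.fledglings for r in data.fecundity])},",
            f"fec_density={vec([r.density for r in data.fecundity], '{:.10g}')}",
        ]
    if data.unbanded:
        parts[-1] += ","
        parts += [
            f"unb_occ={vec([u.occasion + 1 for u in data.unbanded])},",
            f"unb_sex={vec([sex_code[u.sex] for u in data.unbanded])},",
            f"unb_count={vec([u.count for u in data.unbanded])}",
        ]
    parts.append(")")
    path.write_text("\n".join(parts) + "\n")
    return path


def read_dataset(path: str | Path, format: str = "csv-bundle") -> Dataset:
    """Read a dataset from disk.

    Parameters
    ----------
    path
        Directory (``csv-bundle``) or file (``bugs-dump``).
    format
        ``"csv-bundle"`` or ``"bugs-dump"``.
    """
    path = Path(path)
    if format == "csv-bundle":
        if not path.is_dir():
            raise FileNotFoundError(f"{path} is not a csv-bundle directory")
        return _read_csv_bundle(path)
    if format == "bugs-dump":
        if not path.is_file():
            raise FileNotFoundError(f"{path} is not a file")
        return _read_bugs_dump(path)
    raise ValueError(f"unknown format {format!r}")
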