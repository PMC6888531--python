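"""CSV dialects, configuration and report generation.

Two CSV dialects are understood, with units embedded in the column
names to prevent silent unit drift:

* ``raw_batch``:   sample_id, c0_mg_dm3, ce_mg_dm3, v_dm3, m_g
  (converted to equilibrium points through the batch mass balance)
* ``equilibrium``: ce_mg_dm3, qe_mg_g

Configuration is a flat ``key = value`` text file whose keys are
exactly the :class:`RunConfig` fields; unknown keys are rejected with
an actionable message. Reports are emitted both as a machine-readable
CSV (full precision) and as a human-readable table using the rounding
profile (parameters to 4 significant figures, energies to 2 decimals,
percentages to 1 decimal).
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .families import Family, IsothermDataset, ParamSet, celsius_to_kelvin
from .metrics import DEFAULT_MOLAR_MASS, ExperimentRecord, adsorbed_amount
from .result import FitResult

RAW_BATCH_COLUMNS = ("c0_mg_dm3", "ce_mg_dm3", "v_dm3", "m_g")
EQUILIBRIUM_COLUMNS = ("ce_mg_dm3", "qe_mg_g")

_ALL_FAMILIES = tuple(f.value for f in Family)


@dataclass
class RunConfig:
    """Validated run configuration (flat key=value file or CLI flags).

    Temperatures are accepted in Celsius (the batch protocol is stated
    that way) and converted internally to kelvin.
    """

    temperature_c: float = 25.0
    cs_mg_dm3: Optional[float] = None
    molar_mass_g_mol: float = DEFAULT_MOLAR_MASS
    families: Tuple[str, ...] = _ALL_FAMILIES
    method: str = "nonlinear"
    tie_threshold: float = 1.5
    r2_tie: float = 0.01
    multistart: int = 8
    seed: int = 0
    allow_drop: bool = False
    da_search_lower: float = 1.0
    da_search_upper: float = 6.0
    round_params_sig: int = 4
    round_energy_dec: int = 2
    round_percent_dec: int = 1

    def __post_init__(self):
        if self.method not in ("linear", "nonlinear", "both"):
            raise ConfigError(
                f"method must be linear|nonlinear|both, got {self.method!r}"
            )
        bad = [f for f in self.families if f not in _ALL_FAMILIES]
        if bad:
            raise ConfigError(
                f"unknown families {bad!r}; valid: {', '.join(_ALL_FAMILIES)}"
            )
        if self.temperature_c <= -273.15:
            raise ConfigError(f"temperature_c below absolute zero: {self.temperature_c}")
        if self.cs_mg_dm3 is not None and self.cs_mg_dm3 <= 0:
            raise ConfigError(f"cs_mg_dm3 must be > 0, got {self.cs_mg_dm3}")
        if self.molar_mass_g_mol <= 0:
            raise ConfigError(f"molar_mass_g_mol must be > 0, got {self.molar_mass_g_mol}")
        if self.tie_threshold < 1:
            raise ConfigError(f"tie_threshold must be >= 1, got {self.tie_threshold}")
        if self.multistart < 0:
            raise ConfigError(f"multistart must be >= 0, got {self.multistart}")
        if not (0 < self.da_search_lower < self.da_search_upper):
            raise ConfigError(
                f"D-A search bounds invalid: ({self.da_search_lower}, {self.da_search_upper})"
            )

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    def to_text(self) -> str:
        out = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            out.append(f"{f.name} = {v}")
        return "\n".join(out) + "\n"


def load_config(path: Union[str, Path], **overrides) -> RunConfig:
    """Parse a flat key=value config file; keyword overrides win."""
    kv: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        kv[key] = value
    kv.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_mapping(kv, source=str(path))


def config_from_mapping(kv: Mapping[str, object], source: str = "<config>") -> RunConfig:
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(kv) - set(fields))
    if unknown:
        raise ConfigError(
            f"{source}: unknown config keys {unknown}; valid keys: "
            f"{', '.join(sorted(fields))}"
        )
    parsed = {}
    for key, raw in kv.items():
        if raw is None or not isinstance(raw, str):
            parsed[key] = raw
            continue
        try:
            if key == "families":
                parsed[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
            elif key in ("multistart", "seed", "round_params_sig",
                         "round_energy_dec", "round_percent_dec"):
                parsed[key] = int(raw)
            elif key == "allow_drop":
                parsed[key] = raw.lower() in ("1", "true", "yes", "on")
            elif key == "method":
                parsed[key] = raw
            elif key == "cs_mg_dm3" and raw.lower() in ("", "none"):
                parsed[key] = None
            else:
                parsed[key] = float(raw)
        except ValueError as exc:
            raise ConfigError(f"{source}: could not parse {key} = {raw!r}: {exc}") from exc
    return RunConfig(**parsed)


# ---------------------------------------------------------------------------
# Dataset reading/writing
# ---------------------------------------------------------------------------


def detect_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    if set(RAW_BATCH_COLUMNS) <= cols:
        return "raw_batch"
    if set(EQUILIBRIUM_COLUMNS) <= cols:
        return "equilibrium"
    raise ConfigError(
        f"cannot detect CSV dialect from columns {sorted(cols)}; expected "
        f"{RAW_BATCH_COLUMNS} (raw_batch) or {EQUILIBRIUM_COLUMNS} (equilibrium)"
    )


def read_dataset(path: Union[str, Path], dialect: Optional[str] = None, *,
                 temperature: float = 298.15, solubility: Optional[float] = None,
                 sorbent: str = "") -> IsothermDataset:
    """Read an equilibrium dataset from CSV (either dialect).

    Raw-batch rows are converted to (Ce, Qe) through the mass balance
    Qe = (C0 - Ce)*V/m. Validation failures report the offending CSV
    row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    dialect = dialect or detect_dialect(df.columns)
    if dialect == "raw_batch":
        missing = [c for c in RAW_BATCH_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"{path}: raw_batch CSV missing column(s) {missing}")
        ce, qe = [], []
        for i, row in df.iterrows():
            try:
                rec = ExperimentRecord(c0=float(row["c0_mg_dm3"]),
                                       ce=float(row["ce_mg_dm3"]),
                                       volume=float(row["v_dm3"]),
                                       mass=float(row["m_g"]))
            except (InvalidParameterError, ValueError) as exc:
                raise ConfigError(f"{path}: row {i + 1}: {exc}") from exc
            ce.append(rec.ce)
            qe.append(adsorbed_amount(rec))
    elif dialect == "equilibrium":
        missing = [c for c in EQUILIBRIUM_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"{path}: equilibrium CSV missing column(s) {missing}")
        ce = df["ce_mg_dm3"].astype(float).tolist()
        qe = df["qe_mg_g"].astype(float).tolist()
        for i, (c, q) in enumerate(zip(ce, qe)):
            if not np.isfinite(c) or c < 0 or not np.isfinite(q) or q < 0:
                raise ConfigError(
                    f"{path}: row {i + 1}: negative or non-finite value "
                    f"(ce={c!r}, qe={q!r})"
                )
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")
    return IsothermDataset(np.array(ce), np.array(qe), temperature=temperature,
                           solubility=solubility, sorbent=sorbent)


def write_equilibrium_csv(dataset: IsothermDataset, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"ce_mg_dm3": dataset.ce, "qe_mg_g": dataset.qe})
    df.to_csv(path, index=False, float_format="%.17g")


def write_raw_batch_csv(records: Sequence[ExperimentRecord],
                        path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "sample_id": [f"S{i + 1:03d}" for i in range(len(records))],
        "c0_mg_dm3": [r.c0 for r in records],
        "ce_mg_dm3": [r.ce for r in records],
        "v_dm3": [r.volume for r in records],
        "m_g": [r.mass for r in records],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_simulation(prefix: Union[str, Path], dataset: IsothermDataset,
                     records: Sequence[ExperimentRecord], params: ParamSet,
                     design) -> Dict[str, Path]:
    """Write a simulated batch experiment: raw CSV + equilibrium CSV +
    a flat key=value metadata sidecar recording truth and seed."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": prefix.with_name(prefix.name + "_raw.csv"),
        "equilibrium": prefix.with_name(prefix.name + "_equilibrium.csv"),
        "meta": prefix.with_name(prefix.name + "_meta.txt"),
    }
    write_raw_batch_csv(records, paths["raw"])
    write_equilibrium_csv(dataset, paths["equilibrium"])
    meta = [f"family = {params.family.value}"]
    meta += [f"truth_{k} = {v!r}" for k, v in params.as_dict().items()]
    meta += [
        f"volume_dm3 = {design.volume!r}",
        f"mass_g = {design.mass!r}",
        f"temperature_k = {design.temperature!r}",
        f"cs_mg_dm3 = {design.solubility!r}",
        f"noise_cv = {design.noise_cv!r}",
        f"seed = {design.seed}",
        f"replicates = {design.replicates}",
        "c0_schedule_mg_dm3 = " + ",".join(repr(c) for c in design.c0_schedule),
    ]
    paths["meta"].write_text("\n".join(meta) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _sig(value: float, sig: int) -> str:
    return f"{value:.{sig}g}"


def fits_to_frame(fits: Mapping[str, Mapping[Family, FitResult]]) -> pd.DataFrame:
    """Machine-readable long-format table: one row per
    sorbent x family x quantity, full repr precision."""
    rows = []
    for sorbent in fits:
        for fam in sorted(fits[sorbent], key=lambda f: f.value):
            fr = fits[sorbent][fam]
            for name, value in fr.params.as_dict().items():
                rows.append((sorbent, fr.method, fam.value, name, repr(value)))
            if fr.r2 is not None:
                rows.append((sorbent, fr.method, fam.value, "r2", repr(fr.r2)))
            if fr.mpsd is not None:
                rows.append((sorbent, fr.method, fam.value, "mpsd", repr(fr.mpsd)))
    return pd.DataFrame(rows, columns=["sorbent", "method", "family",
                                       "quantity", "value"])


def render_report(fits: Mapping[str, Mapping[Family, FitResult]], *,
                  round_params_sig: int = 4, round_energy_dec: int = 2) -> str:
    """Human-readable table mirroring the usual isotherm-parameter layout."""
    from .metrics import energy_da, energy_dr  # local import avoids cycle at module load

    if not fits or all(not v for v in fits.values()):
        raise ConfigError("render_report: no fits to report")
    buf = _io.StringIO()
    for sorbent in fits:
        per = fits[sorbent]
        if not per:
            continue
        title = f"Isotherm parameters — {sorbent}"
        buf.write(title + "\n" + "=" * len(title) + "\n")
        for fam in sorted(per, key=lambda f: f.value):
            fr = per[fam]
            buf.write(f"{fam.value} ({fr.method}, n={fr.n})\n")
            for name, value in fr.params.as_dict().items():
                buf.write(f"    {name:<6} = {_sig(value, round_params_sig)}\n")
            if fam is Family.DUBININ_RADUSHKEVICH:
                buf.write(f"    E_DR   = {energy_dr(fr.params.k_dr):.{round_energy_dec}f} kJ/mol\n")
            if fam is Family.DUBININ_ASTAKHOV:
                buf.write(f"    E_DA   = "
                          f"{energy_da(fr.params.k_da, fr.params.n_da):.{round_energy_dec}f} kJ/mol\n")
            if fr.r2 is not None:
                buf.write(f"    r^2    = {fr.r2:.4f}\n")
            if fr.mpsd is not None:
                buf.write(f"    MPSD   = {fr.mpsd:.2f}\n")
        buf.write("\n")
    return buf.getvalue()


def write_report(fits: Mapping[str, Mapping[Family, FitResult]],
                 path_prefix: Union[str, Path], *, round_params_sig: int = 4,
                 round_energy_dec: int = 2) -> Dict[str, Path]:
    """Emit the machine CSV and the human table; byte-stable given
    identical inputs."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"csv": prefix.with_name(prefix.name + "_params.csv"),
             "txt": prefix.with_name(prefix.name + "_report.txt")}
    fits_to_frame(fits).to_csv(paths["csv"], index=False)
    paths["txt"].write_text(render_report(fits, round_params_sig=round_params_sig,
                                          round_energy_dec=round_energy_dec))
    return paths
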