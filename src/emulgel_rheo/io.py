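"""CSV/JSON/YAML surfaces, bundled table fixtures, and the analysis pipeline.

Conventions: CSV files are comma-separated UTF-8 with a mandatory header
row.  User-facing tables carry percent columns with an explicit ``_pct``
suffix (as printed); everything internal is fractional.  Sample identifiers
follow the ``Ej.x.y.z`` scheme: energy level j, power level x, fiber weight
percent y (underscore as decimal separator, e.g. ``2_5`` = 2.5%), oil
weight percent z.

The pipeline report records every default the source tables leave open
(density ratio, interfacial tension, droplet radius, dispersed-phase
modulus) so a run is reproducible from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import droplet_psd, emulgel_model, interfacial, suspension_rheology
from .exceptions import ModelDomainError, ValidationError

logger = logging.getLogger("emulgel_rheo")

FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5", "table6")

__all__ = [
    "RunConfig",
    "load_table_fixture",
    "parse_sample_id",
    "read_sweep_csv",
    "read_suspension_series",
    "read_tension_series",
    "read_droplet_diameters",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Defaults and switches for the analysis pipeline.

    All physical values positive; ``psi=None`` means "fit the crowding
    factor", a number means "use it as-is".  ``fractal_dimension=None``
    averages the per-sample values of the suspension table.
    """

    reference_frequency_hz: float = 1.0
    density_ratio: float = emulgel_model.DEFAULT_DENSITY_RATIO
    gamma_mn_per_m: float = 1.40
    radius_um: float | None = None  # None: derive from droplet table
    g_dispersed_pa: float = 11.1
    psi: float | None = None
    psi_bounds: tuple[float, float] = (1e-6, 1000.0)
    fractal_dimension: float | None = None
    d_subset: str = "all"  # or "above_1pct"
    use_storage_from_complex: bool = True
    omega_units: str = "hz"
    plateau_rel_tol: float = 0.25
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reference_frequency_hz", "density_ratio", "gamma_mn_per_m",
                     "g_dispersed_pa"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.radius_um is not None and self.radius_um <= 0:
            raise ValidationError("radius_um must be positive")
        if self.psi is not None and self.psi <= 0:
            raise ValidationError("psi must be positive")
        if self.d_subset not in ("all", "above_1pct"):
            raise ValidationError(f"unknown d_subset {self.d_subset!r}")
        if self.omega_units not in ("hz", "rad_per_s"):
            raise ValidationError(f"unknown omega_units {self.omega_units!r}")
        object.__setattr__(
            self, "psi_bounds", tuple(float(b) for b in self.psi_bounds)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["psi_bounds"] = list(self.psi_bounds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (by extension)."""
        with open(path, "r", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def load_table_fixture(name: str) -> pd.DataFrame:
    """Load one of the bundled printed-table fixtures (``table1``..``table6``).

    Units are normalized on load: percent columns gain a fractional twin
    (``oil_weight_fraction``, ``oil_volume_fraction``); uncertainty columns
    are preserved as printed.
    """
    if name not in FIXTURE_NAMES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    ref = resources.files("emulgel_rheo.data").joinpath(f"{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    if "oil_weight_pct" in df.columns:
        df["oil_weight_fraction"] = df["oil_weight_pct"] / 100.0
    if "oil_volume_pct" in df.columns:
        df["oil_volume_fraction"] = df["oil_volume_pct"] / 100.0
    return df


def parse_sample_id(sample_id: str) -> dict:
    """Parse an ``Ej.x.y.z`` emulgel sample code.

    Returns energy level, power level, fiber percent and oil percent;
    underscores in a field act as decimal separators (``2_5`` -> 2.5).
    """
    parts = sample_id.split(".")
    if len(parts) != 4 or not parts[0].startswith("E"):
        raise ValidationError(f"not an Ej.x.y.z sample id: {sample_id!r}")

    def num(tok: str) -> float:
        return float(tok.replace("_", "."))

    try:
        return {
            "energy_level": int(parts[0][1:]),
            "power_level": int(parts[1]),
            "fiber_pct": num(parts[2]),
            "oil_pct": num(parts[3]),
        }
    except ValueError as exc:
        raise ValidationError(f"cannot parse sample id {sample_id!r}") from exc


# ---------------------------------------------------------------- readers

def read_sweep_csv(path, *, sample_id: str | None = None):
    """Read frequency sweeps from CSV.

    Columns: ``frequency_hz``, ``g_prime_pa``, optional ``g_double_prime_pa``
    and ``sample_id`` (long format).  Returns a single
    :class:`~emulgel_rheo.suspension_rheology.FrequencySweep` when the file
    holds one sample (or ``sample_id`` is given), else a dict keyed by id.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("frequency_hz", "g_prime_pa"), path)

    def build(sub: pd.DataFrame):
        sub = sub.sort_values("frequency_hz")
        loss = (
            sub["g_double_prime_pa"].to_numpy()
            if "g_double_prime_pa" in sub.columns
            else None
        )
        return suspension_rheology.FrequencySweep(
            frequency=sub["frequency_hz"].to_numpy(),
            storage_modulus=sub["g_prime_pa"].to_numpy(),
            loss_modulus=loss,
        )

    if "sample_id" in df.columns:
        if sample_id is not None:
            return build(df[df["sample_id"] == sample_id])
        return {sid: build(sub) for sid, sub in df.groupby("sample_id", sort=False)}
    return build(df)


def read_suspension_series(path) -> suspension_rheology.SuspensionSeries:
    """Read a fiber-fraction series: ``fiber_fraction,g_star_pa,delta_deg``."""
    df = pd.read_csv(path)
    _require_columns(df, ("fiber_fraction", "g_star_pa", "delta_deg"), path)
    return suspension_rheology.SuspensionSeries(
        fiber_fraction=df["fiber_fraction"].to_numpy(),
        modulus=df["g_star_pa"].to_numpy(),
        phase_angle=df["delta_deg"].to_numpy(),
    )


def read_tension_series(path) -> interfacial.TensionSeries:
    """Read an interfacial-tension series:
    ``lecithin_fraction,fiber_fraction,gamma_mn_per_m[,gamma_sd_mn_per_m]``."""
    df = pd.read_csv(path)
    _require_columns(
        df, ("lecithin_fraction", "fiber_fraction", "gamma_mn_per_m"), path
    )
    sd = (
        df["gamma_sd_mn_per_m"].to_numpy()
        if "gamma_sd_mn_per_m" in df.columns
        else None
    )
    return interfacial.TensionSeries(
        lecithin_fraction=df["lecithin_fraction"].to_numpy(),
        fiber_fraction=df["fiber_fraction"].to_numpy(),
        gamma=df["gamma_mn_per_m"].to_numpy(),
        gamma_sd=sd,
    )


def read_droplet_diameters(path) -> dict[str, droplet_psd.DropletPopulation]:
    """Read droplet diameters: ``diameter_um`` plus optional ``sample_id``."""
    df = pd.read_csv(path)
    _require_columns(df, ("diameter_um",), path)
    if "sample_id" in df.columns:
        return {
            str(sid): droplet_psd.DropletPopulation(
                sub["diameter_um"].to_numpy(), sample_id=str(sid)
            )
            for sid, sub in df.groupby("sample_id", sort=False)
        }
    return {"sample": droplet_psd.DropletPopulation(df["diameter_um"].to_numpy())}


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


# --------------------------------------------------------------- pipeline

def run_pipeline(
    config: RunConfig | None = None,
    *,
    suspension_table: pd.DataFrame | None = None,
    emulgel_table: pd.DataFrame | None = None,
    tension_table: pd.DataFrame | None = None,
    droplet_table: pd.DataFrame | None = None,
) -> dict:
    """Run the full characterization chain and return a JSON-able report.

    Stages: fractal analysis of the fiber suspension (average D, lambda'
    fit), plateau interfacial tension, droplet radius, crowding-factor fit
    on the oil-fraction series, and a model-vs-data comparison over the
    fiber-fraction series.  Any table left ``None`` falls back to the
    bundled fixture; pass an empty DataFrame for ``emulgel_table`` to get a
    suspension-only report.
    """
    cfg = config or RunConfig()
    if suspension_table is None:
        suspension_table = load_table_fixture("table1")
    if emulgel_table is None:
        emulgel_table = load_table_fixture("table3")
    if tension_table is None:
        tension_table = load_table_fixture("table4")
    if droplet_table is None:
        droplet_table = load_table_fixture("table5")

    decisions: list[str] = []
    report: dict = {"config": cfg.to_dict(), "decisions": decisions}

    # --- suspension stage ------------------------------------------------
    try:
        sus = _suspension_stage(cfg, suspension_table, decisions)
    except Exception as exc:
        raise type(exc)(f"suspension stage: {exc}") from exc
    report["suspension"] = sus["summary"]

    if emulgel_table is None or len(emulgel_table) == 0:
        logger.info("no emulgel data; suspension-only report")
        return report

    # --- interfacial stage ----------------------------------------------
    try:
        series = interfacial.TensionSeries(
            lecithin_fraction=tension_table["lecithin_fraction"].to_numpy(),
            fiber_fraction=tension_table["fiber_fraction"].to_numpy(),
            gamma=tension_table["gamma_mn_per_m"].to_numpy(),
        )
        plateau = interfacial.plateau_tension(series, cfg.plateau_rel_tol)
        report["interfacial"] = {
            "plateau_gamma_mn_per_m": plateau.gamma,
            "plateau_gamma_sd": plateau.gamma_sd,
            "n_members": len(plateau.members),
            "gamma_used_mn_per_m": cfg.gamma_mn_per_m,
        }
        decisions.append(
            f"interfacial tension for the Palierne kernel taken from config "
            f"({cfg.gamma_mn_per_m} mN/m); recomputed plateau mean is "
            f"{plateau.gamma:.3f} mN/m over {len(plateau.members)} points"
        )
    except Exception as exc:
        raise type(exc)(f"interfacial stage: {exc}") from exc

    # --- droplet stage ---------------------------------------------------
    try:
        radius_um = cfg.radius_um
        if radius_um is None:
            d_rows = droplet_table.copy()
            fiber_pct = d_rows["sample_id"].map(
                lambda s: parse_sample_id(s)["fiber_pct"]
            )
            sel = d_rows[fiber_pct == 3.0]
            radius_um = droplet_psd.mean_droplet_radius(sel["d_s_um"].to_numpy())
            decisions.append(
                f"droplet radius {radius_um:.2f} um = half the mean of the "
                f"{len(sel)} mean diameters measured at 3% fiber"
            )
        report["droplets"] = {"radius_um": radius_um}
    except Exception as exc:
        raise type(exc)(f"droplet stage: {exc}") from exc

    # --- emulgel stage ---------------------------------------------------
    try:
        report["palierne"] = _emulgel_stage(
            cfg, emulgel_table, sus, radius_um, decisions
        )
    except Exception as exc:
        raise type(exc)(f"emulgel stage: {exc}") from exc
    return report


def _suspension_stage(cfg: RunConfig, table: pd.DataFrame, decisions: list) -> dict:
    x = table["fiber_fraction"].to_numpy(dtype=float)
    if cfg.fractal_dimension is not None:
        D, D_sd = cfg.fractal_dimension, 0.0
        decisions.append(f"fractal dimension fixed by config: D = {D}")
    else:
        mask = x > 0.01 if cfg.d_subset == "above_1pct" else np.ones_like(x, bool)
        D, D_sd = suspension_rheology.average_fractal_dimension(
            table.loc[mask, "fractal_dimension"].to_numpy(dtype=float)
        )
        decisions.append(
            f"fractal dimension averaged over the {int(mask.sum())}-row "
            f"'{cfg.d_subset}' subset: D = {D:.3f} +/- {D_sd:.3f}"
        )
    series = suspension_rheology.SuspensionSeries(
        fiber_fraction=x,
        modulus=table["g_star_pa"].to_numpy(dtype=float),
        phase_angle=table["delta_deg"].to_numpy(dtype=float),
    )
    fit = suspension_rheology.fit_fractal_scaling(
        series, D, use_storage_from_complex=cfg.use_storage_from_complex
    )
    return {
        "series": series,
        "table": table,
        "fit": fit,
        "summary": {
            "fractal_dimension": D,
            "fractal_dimension_sd": D_sd,
            "lambda_prime_pa": fit.lambda_prime,
            "r_squared": fit.r_squared,
        },
    }


def _emulgel_stage(
    cfg: RunConfig,
    emulgel_table: pd.DataFrame,
    sus: dict,
    radius_um: float,
    decisions: list,
) -> dict:
    sus_table = sus["table"]

    def g_c_at(x_f: float) -> float:
        match = sus_table[np.isclose(sus_table["fiber_fraction"], x_f)]
        if len(match):
            return float(match["g_star_pa"].iloc[0])
        return float(sus["fit"].predict(x_f)) / np.cos(
            np.radians(np.mean(sus_table["delta_deg"]))
        )

    out: dict = {}
    # crowding-factor fit on the oil-fraction series
    if "series" in emulgel_table.columns:
        oil = emulgel_table[emulgel_table["series"] == "oil"]
        fiber = emulgel_table[emulgel_table["series"] == "fiber"]
    else:
        oil, fiber = emulgel_table, emulgel_table.iloc[0:0]

    psi = cfg.psi
    if len(oil) >= 2:
        x_f_ref = float(oil["fiber_fraction"].iloc[0])
        g_c_ref = g_c_at(x_f_ref)
        pair = emulgel_model.PhasePair.from_io_units(
            g_c=g_c_ref,
            g_d=cfg.g_dispersed_pa,
            gamma_mn_per_m=cfg.gamma_mn_per_m,
            radius_um=radius_um,
        )
        H_ref = emulgel_model.h_parameter(pair)
        phi = _phi_column(oil, cfg)
        g_r = oil["g_star_pa"].to_numpy(dtype=float) / g_c_ref
        out["reference"] = {
            "g_c_pa": g_c_ref,
            "modulus_ratio": pair.modulus_ratio,
            "h_parameter": H_ref,
        }
        if psi is None:
            fit = emulgel_model.fit_psi(phi, g_r, H_ref, bounds=cfg.psi_bounds)
            psi = fit.psi
            out["psi_fit"] = {
                "psi": fit.psi,
                "psi_stderr": fit.psi_stderr,
                "sse": fit.sse,
                "n_points": int(phi.size),
            }
            decisions.append(
                f"crowding factor fitted on the {phi.size}-point oil series: "
                f"psi = {fit.psi:.2f} +/- {fit.psi_stderr:.2f}"
            )
        else:
            decisions.append(f"crowding factor fixed by config: psi = {psi}")
    elif psi is None:
        raise ValidationError("no oil series and no configured psi: cannot model")
    out["psi"] = psi

    # model-vs-data table over the fiber-fraction series
    rows = []
    for _, row in fiber.iterrows():
        x_f = float(row["fiber_fraction"])
        g_c = g_c_at(x_f)
        pair = emulgel_model.PhasePair.from_io_units(
            g_c=g_c,
            g_d=cfg.g_dispersed_pa,
            gamma_mn_per_m=cfg.gamma_mn_per_m,
            radius_um=radius_um,
        )
        H = emulgel_model.h_parameter(pair)
        phi = float(_phi_column(row.to_frame().T, cfg)[0])
        # crossing the denominator pole (possible for H > 0 at large psi*phi)
        # is reported as a non-physical row, mirroring a printed "<0"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                g_r_mod = emulgel_model.gr_modified(H, phi, psi)
                physical = bool(g_r_mod >= 0)
            except ModelDomainError:
                g_r_mod, physical = float("nan"), False
        g_r_exp = float(row["g_star_pa"]) / g_c
        rows.append(
            {
                "sample_id": str(row.get("sample_id", "")),
                "fiber_fraction": x_f,
                "phi": phi,
                "g_c_pa": g_c,
                "g_r_exp": g_r_exp,
                "modulus_ratio": pair.modulus_ratio,
                "h_parameter": H,
                "g_r_model": g_r_mod,
                "physical": physical,
                "error_pct": (g_r_mod - g_r_exp) / g_r_exp * 100.0
                if physical
                else float("nan"),
            }
        )
    out["fiber_series"] = rows
    return out


def _phi_column(df: pd.DataFrame, cfg: RunConfig) -> np.ndarray:
    """Oil volume fractions, preferring printed values over conversion."""
    if "oil_volume_fraction" in df.columns:
        return df["oil_volume_fraction"].to_numpy(dtype=float)
    if "oil_volume_pct" in df.columns:
        return df["oil_volume_pct"].to_numpy(dtype=float) / 100.0
    w = df["oil_weight_fraction"].to_numpy(dtype=float)
    return np.array(
        [emulgel_model.oil_volume_fraction(wi, cfg.density_ratio) for wi in w]
    )


def report_to_json(report: dict, path=None) -> str:
    """Serialize a pipeline report to JSON (numpy-safe)."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    text = json.dumps(report, indent=2, default=default)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
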