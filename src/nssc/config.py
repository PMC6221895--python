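"""Scenario configuration files, curve serialisation and run drivers.

Config format (JSON canonical, YAML accepted)::

    {
      "n": 9,
      "time_units": "coalescent",          # or "years" (needs "scaling")
      "scaling": {"N_ref": 1276, "generation_time": 25,
                  "mutation_rate": 1.25e-8},   # optional
      "sampling": {"demes": [1, 1]},           # optional, 1-based
      "epochs": [
        {"start_time": 0,
         "migration": {"model": "n_island", "n": 9, "M": 1}},
        {"start_time": 0.5,
         "deme_sizes": [1, 1, ...],
         "migration": [[0, 0.5, ...], ...]}    # full matrix, row-major
      ]
    }

Migration is either a full n x n matrix of scaled rates ``M_ij`` or a
named builder with its parameters.  Demes are 1-based in configs and on
the command line, 0-based internally.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import models
from .errors import ConfigError
from .kernel import IICRCurve, iicr, log_time_grid
from .models import ModelEpoch, PiecewiseScenario, TimeScaling, make_scenario
from .simulator import SimulationResult, empirical_iicr, simulate_T
from .state_space import LineageConfiguration, enumerate_states

__all__ = [
    "RunSpec",
    "parse_scenario",
    "load_scenario",
    "scenario_to_dict",
    "save_scenario",
    "write_curve_tsv",
    "run_iicr",
    "run_simulation",
    "emit_fixture",
    "FIXTURES",
]

logger = logging.getLogger("nssc")

_BUILDERS = {
    "n_island": (models.n_island, ("n", "M")),
    "stepping_stone_2d": (models.stepping_stone_2d, ("rows", "cols", "M", "torus")),
    "continent_island": (models.continent_island, ("n", "c", "M")),
}


def _parse_epoch(entry: dict, n: int) -> tuple[float, ModelEpoch]:
    try:
        start = float(entry["start_time"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"epoch needs a numeric 'start_time': {entry!r}") from exc
    mig = entry.get("migration")
    if mig is None:
        raise ConfigError(f"epoch needs a 'migration' entry: {entry!r}")
    if isinstance(mig, dict):
        name = mig.get("model")
        if name not in _BUILDERS:
            raise ConfigError(
                f"unknown migration model {name!r}; "
                f"known: {sorted(_BUILDERS)}"
            )
        fn, keys = _BUILDERS[name]
        kwargs = {k: mig[k] for k in keys if k in mig}
        epoch = fn(**kwargs)
        if "deme_sizes" in entry:
            epoch = ModelEpoch(deme_sizes=np.asarray(entry["deme_sizes"], float),
                               migration=epoch.migration)
    else:
        sizes = entry.get("deme_sizes", [1.0] * n)
        epoch = ModelEpoch(deme_sizes=np.asarray(sizes, float),
                           migration=np.asarray(mig, float))
    if epoch.n != n:
        raise ConfigError(
            f"epoch has {epoch.n} demes but the scenario declares n={n}"
        )
    return start, epoch


def parse_scenario(data: dict) -> PiecewiseScenario:
    """Build a :class:`PiecewiseScenario` from a parsed config mapping."""
    if not isinstance(data, dict):
        raise ConfigError("scenario config must be a mapping")
    try:
        n = int(data["n"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError("config needs an integer deme count 'n'") from exc
    raw_epochs = data.get("epochs")
    if not raw_epochs:
        raise ConfigError("config needs a non-empty 'epochs' list")

    scaling = None
    if "scaling" in data:
        s = data["scaling"]
        try:
            scaling = TimeScaling(
                N_ref=float(s["N_ref"]),
                generation_time=float(s["generation_time"]),
                mutation_rate=float(s.get("mutation_rate", 1.25e-8)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad 'scaling' block: {s!r}") from exc

    units = data.get("time_units", "coalescent")
    if units not in ("coalescent", "years"):
        raise ConfigError(f"time_units must be 'coalescent' or 'years', got {units!r}")
    if units == "years" and scaling is None:
        raise ConfigError("time_units 'years' needs a 'scaling' block")

    parsed = [_parse_epoch(e, n) for e in raw_epochs]
    starts = [p[0] for p in parsed]
    if starts[0] != 0:
        raise ConfigError("the first epoch must have start_time 0")
    change_times = starts[1:]
    if units == "years":
        change_times = [models.scale_time(t, scaling, "to_coalescent")
                        for t in change_times]

    metadata = {}
    if scaling is not None:
        metadata["scaling"] = scaling
    if "sampling" in data:
        metadata["sampling"] = data["sampling"]
    if "name" in data:
        metadata["name"] = data["name"]
    return make_scenario([p[1] for p in parsed], change_times, metadata=metadata)


def load_scenario(path) -> PiecewiseScenario:
    """Load a JSON or YAML scenario config file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return parse_scenario(data)


def scenario_to_dict(scenario: PiecewiseScenario) -> dict:
    """Serialise a scenario (coalescent-unit times, full matrices)."""
    starts = [0.0] + list(scenario.change_times)
    data = {
        "n": scenario.n,
        "time_units": "coalescent",
        "epochs": [
            {
                "start_time": start,
                "deme_sizes": epoch.deme_sizes.tolist(),
                "migration": epoch.migration.tolist(),
            }
            for start, epoch in zip(starts, scenario.epochs)
        ],
    }
    meta = scenario.metadata
    if isinstance(meta.get("scaling"), TimeScaling):
        s = meta["scaling"]
        data["scaling"] = {
            "N_ref": s.N_ref,
            "generation_time": s.generation_time,
            "mutation_rate": s.mutation_rate,
        }
    if "sampling" in meta:
        data["sampling"] = meta["sampling"]
    elif "sampling_deme" in meta:
        d = meta["sampling_deme"]
        data["sampling"] = {"demes": [d, d]}
    if "name" in meta:
        data["name"] = meta["name"]
    return data


def save_scenario(scenario: PiecewiseScenario, path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(scenario), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Run drivers
# ---------------------------------------------------------------------------

@dataclass
class RunSpec:
    """Everything one evaluation run needs.

    ``sampling`` is either the symbolic ``"same"`` / ``"diff"`` (two
    lineages in deme 1, resp. demes 1 and 2) or a list of 1-based deme
    indices, one per lineage.
    """

    scenario: PiecewiseScenario
    sampling: object = "same"
    t_min: float = 1e-3
    t_max: float = 1e2
    points_per_decade: int = 64
    out_curve: object = None
    out_samples: object = None
    scaling: TimeScaling | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise ConfigError("need 0 < t_min < t_max")
        if self.scaling is None:
            s = self.scenario.metadata.get("scaling")
            if isinstance(s, TimeScaling):
                self.scaling = s

    def initial_configuration(self) -> LineageConfiguration:
        n = self.scenario.n
        spec = self.sampling
        if spec == "same":
            demes = [1, 1]
        elif spec == "diff":
            if n < 2:
                raise ConfigError("'diff' sampling needs at least two demes")
            demes = [1, 2]
        else:
            demes = [int(d) for d in spec]
        if len(demes) < 2:
            raise ConfigError("need at least two sampled lineages")
        if any(not 1 <= d <= n for d in demes):
            raise ConfigError(f"sampled demes {demes} outside 1..{n}")
        return LineageConfiguration.different_demes(n, [d - 1 for d in demes])

    def grid(self) -> np.ndarray:
        return log_time_grid(self.t_min, self.t_max, self.points_per_decade)


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "nan"
    return f"{x:.12g}"


def write_curve_tsv(curve: IICRCurve, path, scaling: TimeScaling | None = None,
                    header_comment: str | None = None) -> None:
    """Write a curve as TSV: t, iicr, cdf, pdf (plus t_years if scaled)."""
    cols = ["t", "iicr", "cdf", "pdf"]
    if scaling is not None:
        cols.append("t_years")
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("\t".join(cols))
    for i, t in enumerate(curve.times):
        row = [t, curve.values[i], curve.cdf[i], curve.pdf[i]]
        if scaling is not None:
            row.append(models.scale_time(float(t), scaling, "to_years"))
        lines.append("\t".join(_fmt(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _log_scenario(scenario: PiecewiseScenario) -> None:
    logger.info(
        "scenario%s: n=%d demes, %d epoch(s), change times %s",
        f" '{scenario.metadata['name']}'" if "name" in scenario.metadata else "",
        scenario.n, len(scenario.epochs),
        [round(t, 6) for t in scenario.change_times],
    )


def check_conservation(scenario: PiecewiseScenario) -> None:
    """Warn (never fail) when an epoch violates migrant conservation."""
    for e, epoch in enumerate(scenario.epochs):
        res = models.conservation_residual(epoch)
        worst = float(np.abs(res).max())
        if worst > 1e-9:
            logger.warning(
                "epoch %d violates migrant conservation (max residual %.3g); "
                "the structured coalescent limit still holds", e, worst,
            )


def run_iicr(spec: RunSpec) -> IICRCurve:
    """Evaluate the IICR for a run spec; writes the TSV if requested."""
    scenario = spec.scenario
    _log_scenario(scenario)
    alpha = spec.initial_configuration()
    space = enumerate_states(alpha.total, scenario.n)
    curve = iicr(scenario, space, alpha, spec.grid())
    if spec.out_curve is not None:
        write_curve_tsv(curve, spec.out_curve, scaling=spec.scaling)
        logger.info("wrote curve to %s", spec.out_curve)
    return curve


def run_simulation(spec: RunSpec, n_rep: int) -> tuple[SimulationResult, IICRCurve]:
    """Simulate coalescence times and estimate an empirical IICR."""
    if n_rep < 1:
        raise ConfigError("n_rep must be a positive integer")
    scenario = spec.scenario
    _log_scenario(scenario)
    alpha = spec.initial_configuration()
    space = enumerate_states(alpha.total, scenario.n)
    result = simulate_T(scenario, space, alpha, n_rep, spec.seed)
    times = spec.grid()
    values, cdf_hat = empirical_iicr(result, times)
    curve = IICRCurve(times=times, values=values, cdf=cdf_hat,
                      pdf=np.full(times.shape, np.nan),
                      alpha=alpha, scenario=scenario)
    if spec.out_samples is not None:
        result.save_txt(spec.out_samples)
        logger.info("wrote %d samples to %s", n_rep, spec.out_samples)
    if spec.out_curve is not None:
        write_curve_tsv(curve, spec.out_curve, scaling=spec.scaling,
                        header_comment=f"empirical IICR, n_rep={n_rep}, seed={spec.seed}")
        logger.info("wrote empirical curve to %s", spec.out_curve)
    return result, curve


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("human_neanderthal",)

_FIXTURE_README = """\
# Human / Neanderthal scenario pair

Two scenarios on a shared 10-deme state space, describing humans and
Neanderthals as structured populations descending from a structured
ancestral Homo population.  Times below are calendar years, converted to
coalescent units of 2*N_ref generations in the config files.

Shared parameters
- N_ref = 1276: reference (human) haploid deme size; sets the coalescent
  time scale.
- generation_time = 25 years: an assumed conventional value for Homo
  (a free parameter of the conversion, not an inferred quantity).
- mutation_rate = 1.25e-8 per generation per site: carried for
  sequence-scale conversions.

human.json — 10-deme island model throughout; gene flow M changes
(recent -> ancient): 0.55 (0-192 KYA), 1 (192-287 KYA), 4 (287 KYA-1.1
MYA), 0.55 (1.1-3 MYA), 0.85 (beyond 3 MYA).  Sampling: both lineages in
deme 1.

neanderthal.json — same state space; more recently than the 0.51 MYA
split only a 7-deme block is connected, each deme at 16% of the human
deme size (200/1276 ~ 0.16), with M = 5 (0-192 KYA), 1 (192-287 KYA),
0.5 (287-510 KYA); the other three demes are disconnected and
unreachable (exact block encoding of the split).  From 0.51 MYA backwards
all ten demes are unit-size and connected with the ancestral gene-flow
values 4, 0.55, 0.85 at the same ancestral change times as the human
scenario.  Sampling: both lineages in deme 1 (a Neanderthal-block deme).
"""


def emit_fixture(name: str, out_dir) -> list[Path]:
    """Write the named fixture's scenario configs plus a provenance README."""
    if name not in FIXTURES:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    human, neanderthal = models.human_neanderthal_fixture()
    paths = []
    for scen in (human, neanderthal):
        p = out_dir / f"{scen.metadata['name']}.json"
        save_scenario(scen, p)
        paths.append(p)
    readme = out_dir / "README.md"
    readme.write_text(_FIXTURE_README)
    paths.append(readme)
    return paths
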