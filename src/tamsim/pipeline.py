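"""End-to-end reproduction run: populations -> simulation -> attainment report.

Seed protocol: one master seed per run; every stochastic component gets a
child generator created from the entropy pair ``[master_seed, stream]``
where the stream ids are fixed (groups use their index in the canonical
group order, the covariate pool uses stream 100).  Adding or dropping a
group therefore never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .attainment import (
    DEFAULT_THRESHOLD,
    AttainmentSummary,
    CrossGroupComparison,
    compare_groups,
    render_report,
    summarize_group,
)
from .pk import PKParameters, load_parameters
from .population import (
    GROUP_INDEX,
    GROUPS,
    build_population,
    load_bundled_frequency_tables,
    population_to_frame,
)
from .steady_state import DosingRegimen, results_to_frame, simulate_population
from .synthetic import CovariatePoolSpec, generate_covariate_pool, placeholder_parameters

logger = logging.getLogger("tamsim")

#: Seed-stream id of the covariate pool (groups use 0..8).
POOL_STREAM = 100


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a reproduction run.

    The defaults are the published simulation scenario: all nine groups,
    10,000 patients each, 20 mg once daily (tau 24 h) for 182 days,
    endoxifen threshold 5.97 ng/mL, deterministic quota AS assignment.
    """

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 10_000
    dose: float = 20.0
    tau: float = 24.0
    duration: float = 182.0
    threshold: float = DEFAULT_THRESHOLD
    assignment_mode: str = "quota"
    master_seed: int = 1
    params_path: str | None = None
    out_dir: str = "tamsim_out"
    write_populations: bool = True

    def __post_init__(self) -> None:
        unknown = [g for g in self.groups if g not in GROUP_INDEX]
        if unknown:
            raise ValueError(f"unknown group(s): {unknown}; choose from {GROUPS}")
        if not self.groups:
            raise ValueError("at least one group is required")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.assignment_mode not in ("quota", "multinomial"):
            raise ValueError("assignment_mode must be 'quota' or 'multinomial'")


@dataclass
class RunResult:
    """Artifacts and in-memory outputs of a pipeline run."""

    summaries: list[AttainmentSummary]
    comparison: CrossGroupComparison | None
    params: PKParameters
    out_dir: Path
    paths: dict = field(default_factory=dict)


def _slug(group: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", group.lower()).strip("_")


def run_pipeline(config: RunConfig) -> RunResult:
    """Build, simulate and summarize every configured group; write the report.

    Identical config (including ``master_seed``) yields identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.params_path is not None:
        params = load_parameters(config.params_path)
        params_text = Path(config.params_path).read_bytes()
    else:
        params = placeholder_parameters()
        params_text = json.dumps(params.to_dict(), sort_keys=True).encode()
    if params.is_placeholder:
        logger.warning(
            "simulating with PLACEHOLDER PK parameters — attainment "
            "percentages are not the published results"
        )

    tables = load_bundled_frequency_tables()
    pool = generate_covariate_pool(
        CovariatePoolSpec(seed=[config.master_seed, POOL_STREAM])
    )
    regimen = DosingRegimen(dose=config.dose, tau=config.tau, duration=config.duration)

    pop_dir = out / "populations"
    res_dir = out / "results"
    if config.write_populations:
        pop_dir.mkdir(exist_ok=True)
    res_dir.mkdir(exist_ok=True)

    summaries: list[AttainmentSummary] = []
    for group in config.groups:
        idx = GROUP_INDEX[group]
        logger.info("group %s: building %d patients", group, config.n_per_group)
        patients = build_population(
            tables[group],
            config.n_per_group,
            pool,
            assignment_mode=config.assignment_mode,
            seed=[config.master_seed, idx],
            omega2_cl20=params.omega2_cl20,
            omega2_cl23=params.omega2_cl23,
            id_offset=idx * config.n_per_group,
        )
        results = simulate_population(patients, params, regimen)
        summaries.append(summarize_group(results, patients, config.threshold))
        if config.write_populations:
            population_to_frame(patients).to_csv(
                pop_dir / f"{_slug(group)}.csv", index=False
            )
        results_to_frame(results, patients).to_csv(
            res_dir / f"{_slug(group)}.csv", index=False
        )

    comparison = compare_groups(summaries) if len(summaries) >= 2 else None
    paths = render_report(
        summaries, comparison, out, is_placeholder=params.is_placeholder
    )

    manifest = {
        "config": asdict(config),
        "seed_streams": {
            "groups": {g: GROUP_INDEX[g] for g in config.groups},
            "covariate_pool": POOL_STREAM,
        },
        "params_sha256": hashlib.sha256(params_text).hexdigest(),
        "parameters_are_placeholder": params.is_placeholder,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path

    return RunResult(
        summaries=summaries,
        comparison=comparison,
        params=params,
        out_dir=out,
        paths=paths,
    )
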