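"""End-to-end orchestration: validated run configuration, stage execution
in dependency order, and a reproducible run report.

A single structured YAML config drives a full synthetic run — panel and
genotype simulation feeding the forced-haploid kinship comparison,
sexed chromosome-count simulation feeding Rx, and circular mtDNA read
simulation feeding the liftover/dedup/consensus pipeline. Every
stochastic stage carries its own explicit seed, unknown config keys are
rejected, and the report embeds a hash of the config so identical
configs provably produce identical headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import kinship, mito, sexing, simulate

STAGES = ("kinship", "sexing", "mito")


class ConfigError(ValueError):
    """Invalid run configuration."""


def _check_keys(d: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


def _require_seed(d: Mapping, context: str) -> int:
    if "seed" not in d:
        raise ConfigError(f"stochastic stage {context} requires an explicit seed")
    return int(d["seed"])


@dataclasses.dataclass(frozen=True)
class PanelConfig:
    seed: int
    n_sites: int = 100_000
    freq_min: float = 0.05
    freq_max: float = 0.95

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        _check_keys(d, {"seed", "n_sites", "freq_min", "freq_max"}, "panel")
        return cls(seed=_require_seed(d, "panel"), **{k: v for k, v in d.items() if k != "seed"})


@dataclasses.dataclass(frozen=True)
class KinshipConfig:
    seed: int
    relationship: str = "same_individual"
    n_covered_a: int = 5_000
    n_covered_b: int = 11_000
    overlap_correlation: float = 0.5
    error_rate: float = 0.01
    error_grid: tuple[float, ...] = (0.0, 0.005, 0.01, 0.02)
    n_replicates: int = 2_000

    @classmethod
    def from_dict(cls, d: Mapping) -> "KinshipConfig":
        _check_keys(
            d,
            {
                "seed",
                "relationship",
                "n_covered_a",
                "n_covered_b",
                "overlap_correlation",
                "error_rate",
                "error_grid",
                "n_replicates",
            },
            "kinship",
        )
        seed = _require_seed(d, "kinship")
        kw = {k: v for k, v in d.items() if k != "seed"}
        if "error_grid" in kw:
            kw["error_grid"] = tuple(float(e) for e in kw["error_grid"])
        cfg = cls(seed=seed, **kw)
        if cfg.relationship not in simulate.RELATIONSHIPS:
            raise ConfigError(f"unknown relationship {cfg.relationship!r}")
        return cfg


@dataclasses.dataclass(frozen=True)
class SexingConfig:
    seed: int
    total_reads: int = 100_000

    @classmethod
    def from_dict(cls, d: Mapping) -> "SexingConfig":
        _check_keys(d, {"seed", "total_reads"}, "sexing")
        return cls(seed=_require_seed(d, "sexing"), **{k: v for k, v in d.items() if k != "seed"})


@dataclasses.dataclass(frozen=True)
class MitoConfig:
    seed: int
    reference_seed: int
    reference_length: int = 16_569
    rotation_origin: int | None = None  # default: 8284, scaled down for short circles
    haplotype: tuple[str, ...] = ()
    depth_target: float = 60.0
    mean_length: float = 65.0
    deamination_rate: float = 0.0
    min_mq: int = 30

    @classmethod
    def from_dict(cls, d: Mapping) -> "MitoConfig":
        _check_keys(
            d,
            {
                "seed",
                "reference_seed",
                "reference_length",
                "rotation_origin",
                "haplotype",
                "depth_target",
                "mean_length",
                "deamination_rate",
                "min_mq",
            },
            "mito",
        )
        seed = _require_seed(d, "mito")
        if "reference_seed" not in d:
            raise ConfigError("stochastic stage mito requires an explicit reference_seed")
        kw = {k: v for k, v in d.items() if k != "seed"}
        if "haplotype" in kw:
            kw["haplotype"] = tuple(str(x) for x in kw["haplotype"])
        return cls(seed=seed, **kw)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    panel: PanelConfig
    kinship: KinshipConfig
    sexing: SexingConfig
    mito: MitoConfig
    stages: tuple[str, ...] = STAGES
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _check_keys(
            d, {"panel", "kinship", "sexing", "mito", "stages", "output_dir"}, "run config"
        )
        stages = tuple(d.get("stages", STAGES))
        for s in stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        return cls(
            panel=PanelConfig.from_dict(d.get("panel", {})),
            kinship=KinshipConfig.from_dict(d.get("kinship", {})),
            sexing=SexingConfig.from_dict(d.get("sexing", {})),
            mito=MitoConfig.from_dict(d.get("mito", {})),
            stages=stages,
            output_dir=d.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinship"]["error_grid"] = list(self.kinship.error_grid)
        d["mito"]["haplotype"] = list(self.mito.haplotype)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_demo_config() -> RunConfig:
    """The packaged demonstration configuration (small synthetic run)."""
    from importlib.resources import files

    text = files("hairdna").joinpath("data/demo_config.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Stage runners


def _run_kinship(cfg: RunConfig) -> dict:
    panel = simulate.simulate_panel(
        cfg.panel.n_sites,
        freq_law=("uniform", cfg.panel.freq_min, cfg.panel.freq_max),
        seed=cfg.panel.seed,
    )
    rng = np.random.default_rng(cfg.kinship.seed)
    s_pair, s_mask, s_obs, s_cmp = (int(x) for x in rng.integers(2**31, size=4))
    pair = simulate.simulate_genotype_pair(panel, cfg.kinship.relationship, seed=s_pair)
    mask = simulate.simulate_coverage_mask(
        panel,
        cfg.kinship.n_covered_a,
        cfg.kinship.n_covered_b,
        overlap_correlation=cfg.kinship.overlap_correlation,
        seed=s_mask,
    )
    obs = simulate.sample_observations(
        pair, panel, mask, error_rate=cfg.kinship.error_rate, seed=s_obs
    )
    report = kinship.compare_profiles(
        panel,
        obs[obs["sample_id"] == "A"],
        obs[obs["sample_id"] == "B"],
        error_grid=cfg.kinship.error_grid,
        n_replicates=cfg.kinship.n_replicates,
        seed=s_cmp,
    )
    report["simulated_relationship"] = cfg.kinship.relationship
    return report


def _run_sexing(cfg: RunConfig) -> dict:
    rng = np.random.default_rng(cfg.sexing.seed)
    out = {}
    for sex in ("female", "male"):
        counts = simulate.simulate_chromosome_counts(
            sex, cfg.sexing.total_reads, seed=int(rng.integers(2**31))
        )
        rx = sexing.compute_rx(counts)
        out[sex] = {"simulated_sex": sex, **rx.to_dict()}
    return out


def _run_mito(cfg: RunConfig) -> dict:
    m = cfg.mito
    reference = simulate.random_mt_reference(m.reference_length, seed=m.reference_seed)
    origin = m.rotation_origin
    if origin is None:
        origin = 8284 if m.reference_length >= 8284 else max(2, m.reference_length // 2)
    chim = mito.build_chimeric_reference(reference, rotation_origin=origin)
    readset = simulate.simulate_mt_reads(
        reference,
        haplotype_diffs=m.haplotype,
        depth_target=m.depth_target,
        mean_length=m.mean_length,
        deamination_rate=m.deamination_rate,
        seed=m.seed,
    )
    placements = mito.place_reads_on_chimera(readset, chim)
    retained, accounting = mito.process_placements(placements, chim, min_mq=m.min_mq)
    callset = mito.pileup_and_call(retained, reference)
    profile = mito.haplotype_diff(callset, reference)
    stats = mito.depth_length_stats(callset, retained)
    # a configured substitution that matches the random reference base is a
    # no-op; recovery is judged against the effective difference list
    effective = [
        d
        for d in readset.source_haplotype
        if "." in d or d[-1] != reference[int(d[:-1]) - 1]
    ]
    return {
        "chimeric_length": len(chim.sequence),
        "accounting": accounting,
        "profile": profile,
        "haplotype_recovered": sorted(profile) == sorted(effective),
        "n_heteroplasmies": int(callset.heteroplasmic.sum()),
        "depth_mean": stats.depth_mean,
        "depth_min": stats.depth_min,
        "depth_max": stats.depth_max,
        "depth_sd": stats.depth_sd,
        "mean_fragment_length": stats.mean_length,
    }


_RUNNERS = {"kinship": _run_kinship, "sexing": _run_sexing, "mito": _run_mito}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig | Mapping | str | Path) -> dict:
    """Execute the configured stages and return the run report.

    ``config`` may be a :class:`RunConfig`, a raw mapping, or a path to a
    YAML file. When ``output_dir`` is set, the report is written there as
    ``report.json``. A stage failure aborts the run with the failing
    stage named.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = RunConfig.from_dict(config)
    report: dict = {"config_hash": config.config_hash, "stages": {}}
    for stage in config.stages:
        try:
            report["stages"][stage] = _RUNNERS[stage](config)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report
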