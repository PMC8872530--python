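"""Forced pseudo-haploid relatedness inference from sparse SNP data.

At very low coverage, diploid genotypes cannot be called, so each sample
is reduced to a pseudo-haploid profile: one randomly chosen observed
allele per covered site. Relatedness between two samples is then summarised
by the mismatch proportion — the fraction of sites covered in both
profiles at which the sampled alleles differ. Its expectation decreases
with relatedness: writing p for the alternate-allele frequency and
phi for the kinship coefficient (probability that one allele sampled from
each individual is identical by descent: 1/2 for the same individual, 1/4
for parent-child and full siblings, 0 for unrelated), the per-site
mismatch probability without error is

    m = (1 - phi) * 2 p (1 - p)

i.e. p(1-p) for the same individual, 1.5 p(1-p) for first-degree
relatives and 2 p(1-p) for unrelated pairs. A symmetric observation
error e (each allele flipped independently) transforms this to

    m_obs = m * ((1-e)^2 + e^2) + (1 - m) * 2 e (1 - e).

Because the observed comparison conditions on a particular overlap-site
set, the null distribution of the mismatch proportion is obtained by
Monte-Carlo simulation on exactly that site set, per relationship class
and per plausible error rate, and the observed proportion is classified
by membership of the central 95% replicate intervals.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import RELATIONSHIPS, SNPPanel, sample_pseudohaploid_pairs

VERDICT_OUTSIDE = "inconclusive: outside simulated classes"
VERDICT_AMBIGUOUS = "inconclusive: multiple classes compatible"

#: One minus the kinship coefficient, the per-class factor multiplying
#: 2p(1-p) in the no-error mismatch expectation.
_CLASS_FACTOR = {
    "same_individual": 0.5,
    "parent_child": 0.75,
    "full_siblings": 0.75,
    "unrelated": 1.0,
}


# ---------------------------------------------------------------------------
# Profiles and the mismatch statistic


@dataclasses.dataclass(frozen=True)
class PseudoHaploidProfile:
    """One observed allele per covered site for one sample."""

    sample_id: str
    calls: dict[str, str]

    @property
    def n_sites(self) -> int:
        return len(self.calls)


@dataclasses.dataclass(frozen=True)
class MismatchResult:
    n_overlap: int
    n_mismatch: int

    @property
    def proportion(self) -> float:
        return self.n_mismatch / self.n_overlap


def reduce_to_panel(
    observations: pd.DataFrame, panel: SNPPanel
) -> tuple[pd.DataFrame, int]:
    """Drop observations at sites outside the SNP panel.

    Mirrors the reduction of whole-genome shotgun calls to the ~1.3 M
    marker frame used by genetic-genealogy SNP sets. Duplicate
    observations at one site are retained for downstream sampling.
    Returns the retained table and the number of distinct retained sites.
    """
    keep = observations["site_id"].isin(set(panel.site_ids))
    retained = observations.loc[keep].reset_index(drop=True)
    return retained, retained["site_id"].nunique()


def filter_reads_for_snps(reads: pd.DataFrame) -> pd.DataFrame:
    """Retain read records usable for SNP analysis.

    A read qualifies iff its length is strictly greater than 35 bp (short
    fragments risk spurious mapping of microbial sequences) and its
    mapping quality is at least 30.
    """
    for col in ("length", "mapping_quality"):
        if col not in reads.columns:
            raise ValueError(f"read table missing column {col!r}")
    return reads.loc[
        (reads["length"] > 35) & (reads["mapping_quality"] >= 30)
    ].reset_index(drop=True)


def pseudo_haploidize(
    observations: pd.DataFrame,
    seed: int | None = None,
    sample_id: str | None = None,
) -> PseudoHaploidProfile:
    """Force observations into a pseudo-haploid profile.

    At each site with one or more observations, exactly one is chosen
    uniformly at random; deterministic for a fixed seed.
    """
    if sample_id is None:
        ids = observations["sample_id"].unique() if "sample_id" in observations else ["?"]
        if len(ids) > 1:
            raise ValueError("observations contain multiple samples; pass sample_id")
        sample_id = str(ids[0])
    elif "sample_id" in observations.columns:
        observations = observations.loc[observations["sample_id"] == sample_id]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(observations))
    shuffled = observations.iloc[perm]
    picked = shuffled.drop_duplicates(subset="site_id")
    return PseudoHaploidProfile(
        sample_id=sample_id,
        calls=dict(zip(picked["site_id"], picked["allele"])),
    )


def mismatch_proportion(
    profile_a: PseudoHaploidProfile, profile_b: PseudoHaploidProfile
) -> MismatchResult:
    """Allele mismatch proportion over the sites called in both profiles.

    Symmetric in its arguments and invariant to site ordering; raises if
    the profiles share no called sites (the proportion is undefined).
    """
    common = profile_a.calls.keys() & profile_b.calls.keys()
    if not common:
        raise ValueError("profiles share no called sites; mismatch proportion undefined")
    n_mismatch = sum(1 for s in common if profile_a.calls[s] != profile_b.calls[s])
    return MismatchResult(n_overlap=len(common), n_mismatch=n_mismatch)


# ---------------------------------------------------------------------------
# Expected mismatch: closed form and Monte-Carlo null


def expected_mismatch_closed_form(
    freqs: Sequence[float], relationship: str, error_rate: float = 0.0
) -> float:
    """Panel-average expected mismatch proportion (closed form).

    Per site, ``m = (1 - phi) * 2 p (1-p)`` with the class's kinship
    coefficient phi, then the symmetric error transform
    ``m_obs = m((1-e)^2 + e^2) + (1-m) * 2e(1-e)`` is applied and the
    result averaged over the panel.
    """
    if relationship not in _CLASS_FACTOR:
        raise ValueError(f"unknown relationship: {relationship!r}")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    p = np.asarray(freqs, dtype=float)
    m = _CLASS_FACTOR[relationship] * 2.0 * p * (1.0 - p)
    e = error_rate
    both_or_none = (1 - e) ** 2 + e**2
    exactly_one = 2 * e * (1 - e)
    return float(np.mean(m * both_or_none + (1 - m) * exactly_one))


@dataclasses.dataclass(frozen=True)
class NullSummary:
    relationship: str
    error_rate: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_replicates: int
    replicates: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class MismatchNull:
    """Simulated mismatch-proportion distributions per class x error rate."""

    site_ids: tuple[str, ...]
    relationships: tuple[str, ...]
    error_grid: tuple[float, ...]
    n_replicates: int
    summaries: dict[tuple[str, float], NullSummary]

    def summary(self, relationship: str, error_rate: float) -> NullSummary:
        return self.summaries[(relationship, float(error_rate))]

    def replicates_frame(self) -> pd.DataFrame:
        rows = []
        for (rel, e), s in self.summaries.items():
            if s.replicates is None:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "relationship": rel,
                        "error_rate": e,
                        "replicate": np.arange(s.n_replicates),
                        "mismatch_proportion": s.replicates,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def simulate_mismatch_null(
    freqs: Sequence[float],
    site_ids: Sequence[str] | None = None,
    relationships: Sequence[str] = RELATIONSHIPS,
    error_grid: Sequence[float] = (0.0, 0.005, 0.01, 0.02),
    n_replicates: int = 10_000,
    seed: int | None = None,
    keep_replicates: bool = True,
) -> MismatchNull:
    """Monte-Carlo null distributions of the mismatch proportion.

    ``freqs`` must be the allele frequencies of exactly the overlap-site
    set of the observed comparison: the null is conditional on that set.
    Each replicate draws a fresh genotype pair for the class,
    pseudo-haploidises both genotypes, applies the symmetric observation
    error, and records the mismatch proportion. For each class the same
    underlying draws are reused across the error grid, which makes the
    replicate means exactly monotone in the error rate.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty panel restriction: no overlap sites")
    if n_replicates < 100:
        raise ValueError("n_replicates must be at least 100")
    for e in error_grid:
        if not 0.0 <= e < 0.5:
            raise ValueError("error rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    if site_ids is None:
        site_ids = tuple(f"site{i}" for i in range(p.size))
    summaries: dict[tuple[str, float], NullSummary] = {}
    for rel in relationships:
        hap_a, hap_b = sample_pseudohaploid_pairs(p, rel, n_replicates, rng=rng)
        base = hap_a != hap_b
        u_a = rng.random(base.shape)
        u_b = rng.random(base.shape)
        for e in error_grid:
            flips = (u_a < e) ^ (u_b < e)
            props = (base ^ flips).mean(axis=1)
            lo, hi = np.percentile(props, [2.5, 97.5])
            summaries[(rel, float(e))] = NullSummary(
                relationship=rel,
                error_rate=float(e),
                mean=float(props.mean()),
                sd=float(props.std(ddof=1)),
                ci_low=float(lo),
                ci_high=float(hi),
                n_replicates=int(n_replicates),
                replicates=props.copy() if keep_replicates else None,
            )
    return MismatchNull(
        site_ids=tuple(site_ids),
        relationships=tuple(relationships),
        error_grid=tuple(float(e) for e in error_grid),
        n_replicates=int(n_replicates),
        summaries=summaries,
    )


# ---------------------------------------------------------------------------
# Classification


@dataclasses.dataclass(frozen=True)
class RelatednessCall:
    observed: MismatchResult
    compatible: dict[str, tuple[float, ...]]
    verdict: str

    def to_dict(self) -> dict:
        return {
            "n_overlap": self.observed.n_overlap,
            "n_mismatch": self.observed.n_mismatch,
            "mismatch_proportion": self.observed.proportion,
            "compatible": {k: list(v) for k, v in self.compatible.items()},
            "verdict": self.verdict,
        }


def classify_relationship(observed: MismatchResult, null: MismatchNull) -> RelatednessCall:
    """Classify an observed mismatch proportion against the simulated null.

    A class is compatible at error rate e iff the observed proportion
    lies within that class's central 95% replicate interval. A verdict
    names a class when that class is the only compatible one over some
    contiguous sub-range of the error grid and no other class is
    compatible anywhere on that sub-range; if no class is compatible at
    any error rate the verdict is inconclusive (outside the simulated
    classes), and if several classes have exclusive support the verdict
    is ambiguous.
    """
    if observed.n_overlap != len(null.site_ids):
        raise ValueError(
            "null was not built on the observed overlap-site set "
            f"({observed.n_overlap} observed vs {len(null.site_ids)} null sites)"
        )
    p_obs = observed.proportion
    compatible: dict[str, list[float]] = {rel: [] for rel in null.relationships}
    for (rel, e), s in null.summaries.items():
        if s.ci_low <= p_obs <= s.ci_high:
            compatible[rel].append(e)

    grid = list(null.error_grid)
    exclusive: dict[str, list[float]] = {rel: [] for rel in null.relationships}
    for e in grid:
        holders = [rel for rel in null.relationships if e in compatible[rel]]
        if len(holders) == 1:
            exclusive[holders[0]].append(e)
    candidates = [rel for rel, es in exclusive.items() if es]

    if not any(compatible.values()):
        verdict = VERDICT_OUTSIDE
    elif len(candidates) == 1:
        verdict = candidates[0]
    else:
        verdict = VERDICT_AMBIGUOUS
    return RelatednessCall(
        observed=observed,
        compatible={rel: tuple(sorted(es)) for rel, es in compatible.items()},
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# End-to-end comparison and reporting


def compare_profiles(
    panel: SNPPanel,
    observations_a: pd.DataFrame,
    observations_b: pd.DataFrame,
    error_grid: Sequence[float] = (0.0, 0.005, 0.01, 0.02),
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Full forced-haploid comparison of two observation tables.

    Reduces both tables to the panel, pseudo-haploidises each sample,
    computes the mismatch proportion over the shared sites, simulates the
    conditional null on exactly those sites, and classifies. Returns a
    JSON-serialisable report.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(2**31, size=3))
    obs_a, n_a = reduce_to_panel(observations_a, panel)
    obs_b, n_b = reduce_to_panel(observations_b, panel)
    prof_a = pseudo_haploidize(obs_a, seed=s1)
    prof_b = pseudo_haploidize(obs_b, seed=s2)
    observed = mismatch_proportion(prof_a, prof_b)
    overlap = sorted(prof_a.calls.keys() & prof_b.calls.keys())
    null = simulate_mismatch_null(
        panel.freqs_for(overlap),
        site_ids=overlap,
        error_grid=error_grid,
        n_replicates=n_replicates,
        seed=s3,
    )
    call = classify_relationship(observed, null)
    return {
        "n_sites_a": int(n_a),
        "n_sites_b": int(n_b),
        "n_overlap": observed.n_overlap,
        "mismatch_proportion": observed.proportion,
        "verdict": call.verdict,
        "compatible": {k: list(v) for k, v in call.compatible.items()},
        "null": {
            f"{rel}@{e}": {
                "mean": s.mean,
                "sd": s.sd,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
            for (rel, e), s in null.summaries.items()
        },
        "n_replicates": null.n_replicates,
    }


def write_report_json(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def plot_mismatch_null(null: MismatchNull, observed: MismatchResult | None = None):
    """Violin-style view of the null distributions with the observed line.

    Returns a matplotlib Figure; one panel per error rate, one
    distribution per relationship class, and a dashed horizontal line at
    the observed mismatch proportion.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = null.error_grid
    fig, axes = plt.subplots(1, len(grid), figsize=(3 * len(grid), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, e in zip(axes, grid):
        data = []
        labels = []
        for rel in null.relationships:
            s = null.summary(rel, e)
            if s.replicates is not None:
                data.append(s.replicates)
                labels.append(rel.replace("_", "\n"))
        if data:
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7)
        if observed is not None:
            ax.axhline(observed.proportion, color="red", linestyle="--", lw=1)
        ax.set_title(f"error = {e:g}")
    axes[0].set_ylabel("mismatch proportion")
    fig.tight_layout()
    return fig
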