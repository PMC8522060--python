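"""Per-sample and per-environment statistics of identified glycan genes.

Computes the glycan-gene ratio (identified reads / total reads), CAZy class
composition and exact-match fraction per sample; unweighted means and sample
standard deviations per environment; and the family-prevalence matrix I_ms,
where cell (family, environment) is the fraction of that environment's
samples in which the family was detected (1 = in every sample, 0 = in none).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .identify import SampleResult
from .refdb import CAZY_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class SampleProfile:
    sample_id: str
    environment: str
    total_reads: int
    glycan_reads: int
    ratio: float
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    exact_fraction: float  # NaN when no reads identified


def load_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "environment"}
    if not need.issubset(df.columns):
        raise ValueError(f"sample table {path} must have columns {need}")
    return df


def _environment_of(sample_id: str, env_table: pd.DataFrame) -> str:
    match = env_table.loc[env_table["sample_id"] == sample_id, "environment"]
    if match.empty:
        raise KeyError(f"sample {sample_id} missing from environment table")
    return str(match.iloc[0])


def sample_profile(result: SampleResult,
                   env_table: pd.DataFrame) -> SampleProfile:
    """Summarise one sample's identification result.

    Each identified read contributes one count to the CAZy class of every
    family of its top hit (a single-family subject contributes once). The
    exact fraction is exact-match reads over identified reads, NaN when no
    read was identified.
    """
    env = _environment_of(result.sample_id, env_table)
    n_id = len(result.identified)
    class_counts = {c: 0 for c in CAZY_CLASSES}
    n_exact = 0
    for read in result.identified:
        for cls in read.classes:
            class_counts[cls] += 1
        if read.exact_match:
            n_exact += 1
    total_class = sum(class_counts.values())
    proportions = {
        c: (class_counts[c] / total_class if total_class else math.nan)
        for c in CAZY_CLASSES}
    return SampleProfile(
        sample_id=result.sample_id, environment=env,
        total_reads=result.total_reads, glycan_reads=n_id,
        ratio=n_id / result.total_reads if result.total_reads else 0.0,
        class_counts=class_counts, class_proportions=proportions,
        exact_fraction=n_exact / n_id if n_id else math.nan)


def profiles_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = dict(sample_id=p.sample_id, environment=p.environment,
                   total_reads=p.total_reads, glycan_reads=p.glycan_reads,
                   ratio=p.ratio, exact_fraction=p.exact_fraction)
        for c in CAZY_CLASSES:
            row[f"prop_{c}"] = p.class_proportions[c]
        rows.append(row)
    return pd.DataFrame(rows)


def environment_aggregate(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Unweighted mean and sample SD (n-1) of ratios per environment, plus
    mean class proportions; SD is NaN for single-sample environments."""
    df = profiles_frame(profiles)
    if df.empty:
        return pd.DataFrame(columns=["environment", "n_samples",
                                     "mean_ratio", "sd_ratio"])
    agg = df.groupby("environment").agg(
        n_samples=("sample_id", "size"),
        mean_ratio=("ratio", "mean"),
        sd_ratio=("ratio", lambda s: s.std(ddof=1)),
        mean_exact_fraction=("exact_fraction", "mean"),
        **{f"mean_prop_{c}": (f"prop_{c}", "mean") for c in CAZY_CLASSES},
    ).reset_index()
    return agg


def family_sets(results: Iterable[SampleResult],
                min_reads: int = 1) -> dict[str, set[str]]:
    """Families detected per sample (>= min_reads identified reads)."""
    out: dict[str, set[str]] = {}
    for res in results:
        counts: dict[str, int] = {}
        for read in res.identified:
            for fam in read.families:
                counts[fam] = counts.get(fam, 0) + 1
        out[res.sample_id] = {f for f, n in counts.items() if n >= min_reads}
    return out


def compute_ims(family_sets_per_sample: dict[str, set[str]],
                env_table: pd.DataFrame,
                families: Sequence[str] | None = None) -> pd.DataFrame:
    """The I_ms matrix: families x environments, cells in [0, 1].

    Cell (f, e) = (number of samples of environment e in which family f was
    detected) / (number of samples of environment e). Environments with no
    samples in the input are excluded with a warning.
    """
    env_of = {str(r.sample_id): str(r.environment)
              for r in env_table.itertuples()}
    samples_by_env: dict[str, list[str]] = {}
    for sid in family_sets_per_sample:
        if sid not in env_of:
            raise KeyError(f"sample {sid} missing from environment table")
        samples_by_env.setdefault(env_of[sid], []).append(sid)
    for env in sorted(set(env_of.values()) - set(samples_by_env)):
        logger.warning("environment %s has no samples; excluded", env)
    if families is None:
        families = sorted({f for s in family_sets_per_sample.values()
                           for f in s})
    envs = sorted(samples_by_env)
    data = np.zeros((len(families), len(envs)))
    for j, env in enumerate(envs):
        sids = samples_by_env[env]
        for i, fam in enumerate(families):
            hits = sum(fam in family_sets_per_sample[s] for s in sids)
            data[i, j] = hits / len(sids)
    return pd.DataFrame(data, index=list(families), columns=envs)
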