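"""Seeded generators for protein and PTM fixtures with known ground truth.

The protein generator mirrors the assumptions of the moderated t-test so
that the shrinkage estimator can be validated on its own generative model:
per-feature variances are scaled inverse-chi-square, sigma_g^2 =
s0sq * d0 / chi2_{d0}; log2 abundances are Gaussian around a feature
baseline; a planted fraction of features is shifted by a fixed log2 fold
change in the treatment arm. Intensities are exported exponentiated (raw
scale) so the pipeline's own log2 step is exercised.

The PTM generator draws within-family modification proportions from
Dirichlet distributions whose means differ between groups for planted
modifications, and scales them by a log-normal total family intensity.

Both generators are pure functions of their parameter tuple including the
seed; regenerating with the same arguments is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ptmdiff.io_tables import (
    ModifierDB,
    ProteinMatrix,
    PTMTable,
    SampleMetadata,
    bundled_modifier_db,
)

_HISTONE_SITES = [
    ("H3", "K4"), ("H3", "K9"), ("H3", "K14"), ("H3", "K18"), ("H3", "K23"),
    ("H3", "K27"), ("H3", "K36"), ("H3", "K56"), ("H3.3", "K27"), ("H3.3", "K36"),
    ("H4", "K5"), ("H4", "K8"), ("H4", "K12"), ("H4", "K16"), ("H4", "K20"),
    ("H2A", "K5"), ("H2A", "K9"), ("H2B", "K5"), ("H2B", "K12"), ("H2B", "K15"),
]
_MOD_STATES = ["unmod", "me1", "me2", "me3", "ac", "ph", "ub"]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth sidecar for a simulated dataset."""

    table: pd.DataFrame         # per feature: is_differential, true effect
    d0: float | None
    s0sq: float | None
    n_per_group: int
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def differential_features(self) -> list[str]:
        t = self.table
        return t.loc[t["is_differential"], "feature"].tolist()


def _make_metadata(n_per_group: int, sample_group: str = "Synthetic Tissue"
                   ) -> SampleMetadata:
    rows = []
    for arm in ("Treatment", "Control"):
        for r in range(1, n_per_group + 1):
            rows.append(
                {
                    "file_name": f"Intensity.{arm[0]}{r}",
                    "sample_group": sample_group,
                    "replicate": r,
                    "experimental_group": arm,
                    "custom_id": f"{arm[0]}{r}",
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


def simulate_protein(
    n_features: int = 2000,
    n_per_group: int = 3,
    frac_diff: float = 0.1,
    log2fc_effect: float = 2.0,
    d0: float = 8.0,
    s0sq: float = 0.25,
    seed: int = 0,
    baseline_log2_mean: float = 20.0,
    baseline_log2_sd: float = 2.0,
    missing_rate: float = 0.0,
    n_modifier_genes: int = 6,
    modifier_db: ModifierDB | None = None,
) -> tuple[ProteinMatrix, SampleMetadata, SimTruth]:
    """Simulate a two-group whole-proteome intensity matrix.

    Planted features (a ``frac_diff`` fraction) have their treatment-arm
    mean shifted by ``log2fc_effect`` in log2 space; the sign alternates so
    both up- and down-regulation occur. ``n_modifier_genes`` feature gene
    symbols are drawn from the bundled writer/eraser/reader table so the
    annotation step is exercised. Missingness, when requested, is
    completely at random at rate ``missing_rate``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= frac_diff <= 1:
        raise ValueError("frac_diff must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    n_diff = int(round(frac_diff * n_features))
    is_diff = np.zeros(n_features, dtype=bool)
    is_diff[rng.choice(n_features, size=n_diff, replace=False)] = True
    signs = np.where(np.arange(n_features) % 2 == 0, 1.0, -1.0)
    true_lfc = np.where(is_diff, signs * log2fc_effect, 0.0)

    sigma2 = s0sq * d0 / rng.chisquare(d0, size=n_features)
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_features)

    meta = _make_metadata(n_per_group)
    n_samples = 2 * n_per_group
    noise = rng.normal(0.0, 1.0, size=(n_features, n_samples))
    means = np.tile(baseline[:, None], (1, n_samples))
    means[:, :n_per_group] += true_lfc[:, None]  # treatment arm first
    log2_values = means + noise * np.sqrt(sigma2)[:, None]
    intensities = np.exp2(log2_values)
    if missing_rate > 0:
        mask = rng.random(intensities.shape) < missing_rate
        intensities[mask] = np.nan

    genes = np.array([f"Gene{i + 1}" for i in range(n_features)], dtype=object)
    db = modifier_db or bundled_modifier_db()
    pool = db.for_organism("mouse")["protein_id"].tolist()
    k = min(n_modifier_genes, len(pool), n_features)
    if k:
        slots = rng.choice(n_features, size=k, replace=False)
        picks = rng.choice(len(pool), size=k, replace=False)
        genes[slots] = [pool[j] for j in picks]
    ann = pd.DataFrame(
        {
            "uniprot_id": [f"P{i + 1:05d}" for i in range(n_features)],
            "gene_id": genes,
            "description": [f"Synthetic protein {i + 1}" for i in range(n_features)],
        }
    )
    ann.index = pd.Index(ann["uniprot_id"], name="feature")
    inten = pd.DataFrame(
        intensities,
        index=ann.index,
        columns=meta.table["file_name"].tolist(),
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "feature": ann.index,
                "gene_id": genes,
                "is_differential": is_diff,
                "true_log2fc": true_lfc,
            }
        ),
        d0=d0,
        s0sq=s0sq,
        n_per_group=n_per_group,
        seed=seed,
    )
    return ProteinMatrix(ann, inten), meta, truth


def simulate_ptm(
    families: list[int] | None = None,
    n_per_group: int = 3,
    planted_shifts: dict[tuple[int, int], float] | None = None,
    intensity_scale: float = 1e6,
    concentration: float = 200.0,
    seed: int = 0,
) -> tuple[PTMTable, SampleMetadata, SimTruth]:
    """Simulate a histone-PTM intensity table with planted beta shifts.

    ``families`` lists family sizes (modification states per site);
    ``planted_shifts`` maps (family index, member index) to the additive
    change in that modification's mean proportion in the treatment arm
    (the other members absorb the opposite change proportionally).
    ``concentration`` controls replicate noise (Dirichlet concentration of
    the per-sample proportions); total family intensity is log-normal with
    median ``intensity_scale``.
    """
    families = families if families is not None else [4, 3, 5, 2, 4]
    planted_shifts = planted_shifts or {}
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for (fi, mi), delta in planted_shifts.items():
        if fi >= len(families) or mi >= families[fi]:
            raise ValueError(f"planted shift index out of range: {(fi, mi)}")
    rng = np.random.default_rng(seed)
    meta = _make_metadata(n_per_group, sample_group="Synthetic Histone Prep")
    n_samples = 2 * n_per_group

    rows, inten_rows, truth_rows = [], [], []
    for fi, size in enumerate(families):
        if size < 1:
            raise ValueError("family sizes must be >= 1")
        histone, site = _HISTONE_SITES[fi % len(_HISTONE_SITES)]
        if fi >= len(_HISTONE_SITES):  # keep (histone, site) families distinct
            site = f"{site}x{fi // len(_HISTONE_SITES)}"
        mods = [_MOD_STATES[m % len(_MOD_STATES)] for m in range(size)]
        base = rng.dirichlet(np.full(size, 5.0))
        mean_ctrl = base.copy()
        mean_trt = base.copy()
        for (pfi, pmi), delta in planted_shifts.items():
            if pfi != fi:
                continue
            mean_trt[pmi] += delta
            others = [j for j in range(size) if j != pmi]
            if others:
                rest = base[others].sum()
                if rest > 0:
                    mean_trt[others] -= delta * base[others] / rest
        if size > 1 and (np.any(mean_trt <= 0) or np.any(mean_trt >= 1)):
            raise ValueError(
                f"planted shift in family {fi} pushes a mean proportion "
                f"outside (0, 1): {np.round(mean_trt, 4).tolist()}"
            )
        totals = intensity_scale * np.exp(rng.normal(0.0, 0.3, size=n_samples))
        props = np.empty((size, n_samples))
        for s in range(n_samples):
            mean = mean_trt if s < n_per_group else mean_ctrl  # treatment first
            if size == 1:
                props[:, s] = 1.0
            else:
                props[:, s] = rng.dirichlet(concentration * mean)
        fam_inten = props * totals[None, :]
        for m in range(size):
            rows.append(
                {"histone_protein": histone, "site": site, "modification": mods[m]}
            )
            inten_rows.append(fam_inten[m])
            truth_rows.append(
                {
                    "feature": f"{histone}{site}{mods[m]}",
                    "family": fi,
                    "is_differential": (fi, m) in planted_shifts,
                    "true_beta_control": mean_ctrl[m],
                    "true_beta_treatment": mean_trt[m],
                }
            )

    ann = pd.DataFrame(rows)
    inten = pd.DataFrame(
        np.vstack(inten_rows), columns=meta.table["file_name"].tolist()
    )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows),
        d0=None,
        s0sq=None,
        n_per_group=n_per_group,
        seed=seed,
    )
    return PTMTable(ann, inten), meta, truth


def write_fixture(
    out_dir: str | Path,
    kind: str,
    seed: int = 0,
    **params,
) -> dict[str, Path]:
    """Write a simulated dataset plus metadata and truth sidecar as CSVs.

    Returns the file manifest. The CSVs use exactly the dialects the
    readers consume; the truth sidecar is a separate file, never embedded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "protein":
        matrix, meta, truth = simulate_protein(seed=seed, **params)
    elif kind == "ptm":
        matrix, meta, truth = simulate_ptm(seed=seed, **params)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    paths = {
        "data": out_dir / f"{kind}_data.csv",
        "metadata": out_dir / f"{kind}_metadata.csv",
        "truth": out_dir / f"{kind}_truth.csv",
    }
    matrix.to_csv(paths["data"])
    meta.table.to_csv(paths["metadata"], index=False)
    truth.to_csv(paths["truth"])
    return paths
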