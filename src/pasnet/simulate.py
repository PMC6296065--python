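"""Synthetic expression/clinical/pathway fixtures with planted signal.

The generator emulates the regime the model targets: high-dimension
low-sample-size standardized expression, a minority long-survival class
(~20%), and signal organized by pathways — member genes of a few
"informative" pathways have their means shifted by ``effect_size``
standard-deviation units in the minority class, on top of i.i.d.
Gaussian noise.  Survival times are drawn so that labelling at 24
months reproduces the designed classes exactly, plus a small
censored-alive-under-cutoff tail to exercise exclusion.  It makes no
attempt at RNA-seq count distributions or realistic gene–gene
correlation; a latent pathway-factor mode is deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationDesign", "SimulatedDataset", "simulate_dataset", "simulate"]


@dataclass
class SimulationDesign:
    """Parameters of one simulated cohort.

    ``n_samples`` counts labelled samples only; censored samples are an
    additional ``censored_fraction`` tail.  ``effect_size`` is the mean
    shift, in units of ``noise_sd``, applied to informative-pathway
    member genes in the minority (long-survival) class.
    ``overlap_fraction`` is the fraction of each pathway's genes drawn
    from genes already assigned to earlier pathways.
    """

    n_samples: int = 300
    n_genes: int = 400
    n_pathways: int = 25
    genes_per_pathway: tuple[int, int] = (16, 16)
    n_informative_pathways: int = 3
    effect_size: float = 1.0
    minority_fraction: float = 0.2
    noise_sd: float = 1.0
    overlap_fraction: float = 0.0
    censored_fraction: float = 0.05
    cutoff_months: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must lie in (0, 0.5]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_informative_pathways > self.n_pathways:
            raise ValueError("more informative pathways than pathways")
        lo, hi = self.genes_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("invalid genes_per_pathway range")


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame       # all samples (incl. censored) × genes
    clinical: pd.DataFrame         # sample_id, survival_months, status
    memberships: list[tuple[str, list[str]]]
    truth: dict


def _memberships(design: SimulationDesign, rng) -> list[tuple[str, list[str]]]:
    gene_names = [f"G{j:04d}" for j in range(design.n_genes)]
    pool = list(rng.permutation(design.n_genes))
    ptr = 0
    used: list[int] = []
    lo, hi = design.genes_per_pathway
    out = []
    for i in range(design.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_old = min(int(np.floor(size * design.overlap_fraction)), len(used))
        old = list(rng.choice(used, n_old, replace=False)) if n_old else []
        n_new = size - n_old
        if ptr + n_new > design.n_genes:
            raise ValueError(
                "infeasible design: pathways require more distinct genes "
                f"than n_genes={design.n_genes}"
            )
        new = pool[ptr: ptr + n_new]
        ptr += n_new
        used.extend(new)
        out.append((f"PW{i:03d}", sorted(gene_names[j] for j in old + new)))
    return out


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate one cohort according to the design (deterministic in seed)."""
    rng = np.random.default_rng(design.seed)
    memberships = _memberships(design, rng)
    gene_names = [f"G{j:04d}" for j in range(design.n_genes)]

    n = design.n_samples
    n_min = int(round(n * design.minority_fraction))
    if n_min < 1 or n - n_min < 1:
        raise ValueError("minority_fraction leaves an empty class")
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_min]] = 1  # 1 = LTS minority

    info_idx = sorted(
        rng.choice(design.n_pathways, design.n_informative_pathways, replace=False)
    )
    info_pathways = [memberships[i][0] for i in info_idx]
    info_genes = sorted({g for i in info_idx for g in memberships[i][1]})
    gcol = {g: j for j, g in enumerate(gene_names)}
    info_cols = [gcol[g] for g in info_genes]

    n_cens = int(round(design.censored_fraction * n))
    total = n + n_cens
    X = rng.normal(0.0, design.noise_sd, size=(total, design.n_genes))
    X[np.flatnonzero(y == 1)[:, None], info_cols] += (
        design.effect_size * design.noise_sd
    )

    cutoff = design.cutoff_months
    survival = np.empty(total)
    deceased = np.empty(total, dtype=bool)
    survival[:n][y == 1] = cutoff + rng.uniform(0.0, 1.5 * cutoff, n_min)
    deceased[:n][y == 1] = rng.random(n_min) < 0.5
    survival[:n][y == 0] = rng.uniform(0.0, cutoff * 0.999, n - n_min)
    deceased[:n][y == 0] = True
    survival[n:] = rng.uniform(0.0, cutoff * 0.999, n_cens)
    deceased[n:] = False

    ids = [f"SAMP{i:04d}" for i in range(total)]
    expression = pd.DataFrame(
        X, index=pd.Index(ids, name="sample_id"), columns=gene_names
    )
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "survival_months": np.round(survival, 4),
            "status": np.where(deceased, "deceased", "alive"),
        }
    )
    truth = {
        "design": asdict(design),
        "informative_pathways": info_pathways,
        "informative_genes": info_genes,
        "labels": {ids[i]: int(y[i]) for i in range(n)},
        "censored_ids": ids[n:],
        "n_lts": int(n_min),
        "n_non_lts": int(n - n_min),
        "n_censored": int(n_cens),
    }
    return SimulatedDataset(expression, clinical, memberships, truth)


def simulate(design: SimulationDesign, out_dir) -> dict[str, Path]:
    """Generate a cohort and write expression/clinical/GMT/truth files."""
    ds = simulate_dataset(design)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "truth.json",
    }
    ds.expression.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    ds.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with open(paths["gmt"], "w", encoding="utf-8") as fh:
        for name, genes in ds.memberships:
            fh.write("\t".join([name, "simulated"] + list(genes)) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(ds.truth, fh, indent=1, default=str)
    return paths
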