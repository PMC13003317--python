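"""Simulation study: planted CNF phenotypes in a line-up of decoy SNPs.

Each simulated dataset contains ``P`` independent binary phenotypes, a
planted (K,L)-CNF combined phenotype, and ``n_snps`` genotype columns: one
*pseudo-SNP* equal to the planted CNF's indicator with a fraction ``eps`` of
entries logically negated (adversarial noise), and ``n_snps - 1`` *decoy*
SNPs drawn independently at the pseudo-SNP's empirical carrier frequency, so
they are frequency-matched but carry no true association.

A method run succeeds on a dataset when it picks the pseudo-SNP out of the
line-up: the pseudo-SNP must reach the Bonferroni-corrected threshold
``0.05 / n_snps`` in the discovery half and again (with the fixed fitted
CNF) in the validation half.  Decoys reaching the threshold are false
positives; a pseudo-SNP missing it in discovery is a false negative.

The full factorial grid crosses K, L in {1,2,3}, subjects M in
{2000, 20000, 200000} and eps in {0, 0.1, 0.2} - 81 settings.  ``run_grid``
accepts any subset of it (and any trial count), so reduced pilots use the
same code path as the full design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import BinaryMatrix, CNFPhenotype
from .ilp_core import evaluate_cnf
from .search import gwas_baseline, two_stage

__all__ = [
    "SimulationSpec",
    "SimulationDataset",
    "generate_dataset",
    "grid_settings",
    "run_grid",
    "summarize",
    "classify_trial",
]

GRID_K = (1, 2, 3)
GRID_L = (1, 2, 3)
GRID_M = (2000, 20000, 200000)
GRID_EPS = (0.0, 0.1, 0.2)

PREVALENCE_RANGE = (0.01, 0.2)
DECOY_FREQ_BAND = 0.2  # decoy carrier frequency within +-20% of the pseudo-SNP


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset."""

    K: int
    L: int
    M: int
    eps: float
    P: int = 11
    n_snps: int = 50
    pheno_prevalences: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.L < 1 or self.M < 2 or not 0 <= self.eps < 1:
            raise ValueError("invalid simulation parameters")
        if self.L > self.P:
            raise ValueError("clause size exceeds phenotype count")


@dataclass(frozen=True)
class SimulationDataset:
    X: BinaryMatrix
    Y: BinaryMatrix
    truth: CNFPhenotype
    pseudo_snp_id: str
    flipped: tuple[int, ...] = field(repr=False)
    spec: SimulationSpec = None


def _draw_cnf(rng: np.random.Generator, P: int, K: int, L: int,
              Y: np.ndarray, max_attempts: int = 100) -> CNFPhenotype:
    """Uniformly draw K distinct clauses of L distinct phenotypes; redraw
    when the evaluation is constant over the subjects."""
    for _ in range(max_attempts):
        clauses: set[frozenset[int]] = set()
        guard = 0
        while len(clauses) < K and guard < 1000:
            clauses.add(frozenset(rng.choice(P, size=L, replace=False).tolist()))
            guard += 1
        if len(clauses) < K:
            continue
        ordered = sorted(tuple(sorted(c)) for c in clauses)
        cnf = CNFPhenotype(tuple(frozenset(c) for c in ordered))
        ind = evaluate_cnf(cnf, Y)
        if 0 < ind.sum() < len(ind):
            return cnf
    raise RuntimeError(
        f"could not draw a non-constant ({K},{L})-CNF in {max_attempts} "
        "attempts; phenotype prevalences may be too extreme"
    )


def generate_dataset(spec: SimulationSpec) -> SimulationDataset:
    """Generate one dataset; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.pheno_prevalences is None:
        prev = rng.uniform(*PREVALENCE_RANGE, size=spec.P)
    else:
        prev = np.asarray(spec.pheno_prevalences, dtype=float)
        if prev.shape != (spec.P,):
            raise ValueError("prevalence vector length must equal P")
    Y = (rng.random((spec.M, spec.P)) < prev).astype(np.int8)
    truth = _draw_cnf(rng, spec.P, spec.K, spec.L, Y)
    pseudo = evaluate_cnf(truth, Y).copy()
    n_flips = round(spec.eps * spec.M)
    flipped = rng.choice(spec.M, size=n_flips, replace=False) if n_flips \
        else np.array([], dtype=int)
    pseudo[flipped] = 1 - pseudo[flipped]
    freq = pseudo.mean()
    decoys = np.empty((spec.M, spec.n_snps - 1), dtype=np.int8)
    lo, hi = freq * (1 - DECOY_FREQ_BAND), freq * (1 + DECOY_FREQ_BAND)
    for d in range(spec.n_snps - 1):
        for _ in range(50):
            col = (rng.random(spec.M) < freq).astype(np.int8)
            if lo <= col.mean() <= hi:
                break
        decoys[:, d] = col
    pos = int(rng.integers(spec.n_snps))
    X = np.insert(decoys, pos, pseudo, axis=1)
    width = len(str(spec.n_snps - 1))
    snp_ids = tuple(f"snp{j:0{width}d}" for j in range(spec.n_snps))
    subj_ids = tuple(f"s{i}" for i in range(spec.M))
    pheno_ids = tuple(f"ph{j}" for j in range(spec.P))
    return SimulationDataset(
        X=BinaryMatrix(X, subj_ids, snp_ids, kind="genotype"),
        Y=BinaryMatrix(Y, subj_ids, pheno_ids, kind="phenotype"),
        truth=truth.canonical(),
        pseudo_snp_id=snp_ids[pos],
        flipped=tuple(int(i) for i in np.sort(flipped)),
        spec=spec,
    )


def grid_settings() -> list[dict]:
    """The full factorial design: 81 (K, L, M, eps) settings."""
    return [
        {"K": K, "L": L, "M": M, "eps": eps}
        for K, L, M, eps in itertools.product(GRID_K, GRID_L, GRID_M, GRID_EPS)
    ]


def _trial_seed(master_seed: int, setting_index: int, trial: int,
                stream: int = 0) -> int:
    """Counter-derived per-trial seed, re-derivable for any single trial."""
    ss = np.random.SeedSequence([master_seed, setting_index, trial, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def classify_trial(results, pseudo_snp_id: str, snp_ids) -> pd.DataFrame:
    """Per-SNP outcome of one method run: a SNP counts as passing a stage if
    either orientation (plain or negated) passes it."""
    disc: dict[str, bool] = {s: False for s in snp_ids}
    val: dict[str, bool] = {s: False for s in snp_ids}
    for r in results:
        if r.status in ("optimized", "validated"):
            disc[r.snp_id] = True
        if r.status == "validated":
            val[r.snp_id] = True
    rows = [
        {"snp_id": s, "is_pseudo": int(s == pseudo_snp_id),
         "discovery_pass": int(disc[s]), "validation_pass": int(val[s])}
        for s in snp_ids
    ]
    return pd.DataFrame(rows)


def run_grid(
    trials_per_setting: int,
    methods: tuple[str, ...] = ("reversegwas", "gwas"),
    out_dir: str | Path | None = None,
    settings: list[dict] | None = None,
    master_seed: int = 0,
    n_snps: int = 50,
    P: int = 11,
    p0: float | None = None,
    negate: bool = False,
    backend=None,
    time_limit: float | None = None,
) -> pd.DataFrame:
    """Run the simulation design and classify every SNP in every trial.

    ``p0`` defaults to the Bonferroni-corrected threshold ``0.05 / n_snps``.
    Negated variants are off by default here: the planted pseudo-SNP is
    positively associated by construction, so the protective-direction scan
    (a real-data device) would only double the line-up.  Per-trial failures
    are recorded without aborting the grid.  Returns the long-format outcome
    table; with ``out_dir`` set, one TSV per setting plus the aggregate
    table and a plain-text config are written.
    """
    if settings is None:
        settings = grid_settings()
    if p0 is None:
        p0 = 0.05 / n_snps
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = [f"trials={trials_per_setting}", f"n_snps={n_snps}", f"P={P}",
               f"p0={p0}", f"master_seed={master_seed}",
               f"methods={','.join(methods)}", f"negate={negate}"]
        (out_dir / "config.txt").write_text("\n".join(cfg) + "\n")
    all_rows = []
    for s_idx, setting in enumerate(settings):
        setting_rows = []
        for trial in range(trials_per_setting):
            seed = _trial_seed(master_seed, s_idx, trial, 0)
            split_seed = _trial_seed(master_seed, s_idx, trial, 1)
            spec = SimulationSpec(K=setting["K"], L=setting["L"],
                                  M=setting["M"], eps=setting["eps"],
                                  P=P, n_snps=n_snps, seed=seed)
            try:
                ds = generate_dataset(spec)
            except RuntimeError as exc:
                setting_rows.append(pd.DataFrame([{
                    "snp_id": "", "is_pseudo": 0, "discovery_pass": 0,
                    "validation_pass": 0, "method": m, "error": str(exc),
                    "trial": trial}
                    for m in methods]))
                continue
            for method in methods:
                if method == "reversegwas":
                    results = two_stage(ds.X, ds.Y, spec.K, spec.L, p0,
                                        split_seed, negate=negate,
                                        backend=backend,
                                        time_limit=time_limit)
                elif method == "gwas":
                    results = gwas_baseline(ds.X, ds.Y, p0, split_seed,
                                            negate=negate)
                else:
                    raise ValueError(f"unknown method {method!r}")
                cls = classify_trial(results, ds.pseudo_snp_id, ds.X.col_ids)
                cls["method"] = method
                cls["error"] = ""
                cls["trial"] = trial
                setting_rows.append(cls)
        frame = pd.concat(setting_rows, ignore_index=True)
        for key, val in setting.items():
            frame[key] = val
        all_rows.append(frame)
        if out_dir is not None:
            name = (f"setting_K{setting['K']}_L{setting['L']}"
                    f"_M{setting['M']}_eps{setting['eps']}.tsv")
            frame.to_csv(out_dir / name, sep="\t", index=False)
    outcomes = pd.concat(all_rows, ignore_index=True)
    if out_dir is not None:
        outcomes.to_csv(out_dir / "outcomes.tsv", sep="\t", index=False)
    return outcomes


def summarize(outcomes: pd.DataFrame,
              facets: tuple[str, ...] = ("K", "L", "M", "eps")) -> dict:
    """Aggregate true/false-positive and false-negative rates.

    Counts are reported with explicit denominators.  Per method:

    * ``tpr_two_stage`` — pseudo-SNPs passing both stages / pseudo-SNP trials,
    * ``fn_rate``       — pseudo-SNPs missing the discovery threshold,
    * ``fp_rate_discovery`` — decoys passing discovery / decoy tests,
    * ``validated_fp``  — decoys passing both stages (count and rate),
    * ``validation_rate_among_discovered`` — validated pseudo / discovered.
    """
    out: dict = {"methods": {}, "facets": {}}
    for method, grp in outcomes.groupby("method"):
        pseudo = grp[grp["is_pseudo"] == 1]
        decoy = grp[grp["is_pseudo"] == 0]
        n_pseudo = len(pseudo)
        n_disc = int(pseudo["discovery_pass"].sum())
        n_val = int(pseudo["validation_pass"].sum())
        n_decoy = len(decoy)
        out["methods"][method] = {
            "n_pseudo_trials": n_pseudo,
            "n_decoy_tests": n_decoy,
            "tp_two_stage": n_val,
            "tpr_two_stage": n_val / n_pseudo if n_pseudo else float("nan"),
            "fn": n_pseudo - n_disc,
            "fn_rate": (n_pseudo - n_disc) / n_pseudo if n_pseudo
            else float("nan"),
            "fp_discovery": int(decoy["discovery_pass"].sum()),
            "fp_rate_discovery": (decoy["discovery_pass"].mean()
                                  if n_decoy else float("nan")),
            "validated_fp": int(decoy["validation_pass"].sum()),
            "validated_fp_rate": (decoy["validation_pass"].mean()
                                  if n_decoy else float("nan")),
            "discovered": n_disc,
            "validation_rate_among_discovered":
                n_val / n_disc if n_disc else float("nan"),
        }
    for facet in facets:
        if facet not in outcomes.columns:
            continue
        rows = []
        for (method, fval), grp in outcomes.groupby(["method", facet]):
            pseudo = grp[grp["is_pseudo"] == 1]
            rows.append({
                "method": method, facet: fval,
                "n": len(pseudo),
                "tp_two_stage": int(pseudo["validation_pass"].sum()),
                "tpr_two_stage": pseudo["validation_pass"].mean()
                if len(pseudo) else float("nan"),
            })
        out["facets"][facet] = pd.DataFrame(rows)
    return out
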