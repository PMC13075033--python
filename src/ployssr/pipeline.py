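"""End-to-end orchestration of the analysis flow on one genotype table.

Stages: validation -> per-locus diversity and identity statistics ->
distance matrices (combined Bruvo/Jaccard and Nei) -> bootstrapped UPGMA
tree -> minimum spanning network -> PCoA -> group permutation tests ->
Evanno summaries when a run-likelihood table is supplied.  Every output is
also reachable through the corresponding subcommand; the pipeline only
sequences them, funnels all randomness through one recorded seed, and writes
a manifest (versions, seeds, config hash) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import bootstrap_support, minimum_spanning_network
from .distance import FillModel, combined_matrix, nei_distance_matrix
from .diversity import (
    all_locus_stats,
    group_summaries,
    mean_stats,
    probability_of_identity,
)
from .genotypes import GroupAssignment, read_genotypes, validate
from .ordination import group_mean_distances, pcoa, permutation_tests
from .structure import LikelihoodTable, evanno

log = logging.getLogger("ployssr")

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    genotypes: str
    loci: str
    out_dir: str
    groups: Optional[str] = None
    runs: Optional[str] = None
    ploidy: int = 4
    fill_model: str = FillModel.ADDITION_LOSS_AVERAGE.value
    bootstrap_reps: int = 1000
    bootstrap_threshold_pct: float = 40.0
    n_permutations: int = 1999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stats_frame(stats) -> pd.DataFrame:
    rows = [
        {
            "locus": s.locus,
            "Na": s.Na,
            "Ne": round(s.Ne, 3),
            "PA": s.PA,
            "PIC": round(s.PIC, 3),
            "Hprime": round(s.Hprime, 3),
            "Rp": round(s.Rp, 3),
        }
        for s in stats
    ]
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a result bundle of in-memory objects.

    Any stage failure aborts with the stage name and cause; outputs written
    before the failure are retained next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest = {
        "ployssr_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "setup"
    t_total = time.time()
    try:
        def _begin(name: str):
            nonlocal stage
            stage = name
            log.info("stage %s ...", name)
            return time.time()

        def _end(name: str, t0: float, **info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

        t0 = _begin("read")
        table = read_genotypes(config.genotypes, config.loci, ploidy=config.ploidy)
        groups = None
        if config.groups:
            groups = GroupAssignment.from_csv(config.groups)
            groups.validate_against(table)
        elif any(a.group for a in table):
            groups = GroupAssignment.from_table(table)
        bundle["table"], bundle["groups"] = table, groups
        _end("read", t0, n_accessions=len(table), n_loci=len(table.loci))

        t0 = _begin("validate")
        diags = validate(table)
        pd.DataFrame([d.__dict__ for d in diags]).to_csv(out / "diagnostics.csv", index=False)
        bundle["diagnostics"] = diags
        _end("validate", t0, n_diagnostics=len(diags))

        t0 = _begin("diversity")
        stats = all_locus_stats(table)
        frame = _stats_frame(stats)
        means = mean_stats(stats)
        frame.loc[len(frame)] = ["Mean"] + [
            round(means[m], 3) for m in ("Na", "Ne", "PA", "PIC", "Hprime", "Rp")
        ]
        frame.to_csv(out / "locus_stats.csv", index=False)
        ident = probability_of_identity(table)
        with open(out / "identity.json", "w") as fh:
            json.dump(
                {"PI": ident.PI, "PD": ident.PD, "per_locus_PI": ident.per_locus_PI},
                fh,
                indent=2,
            )
        bundle["locus_stats"], bundle["identity"] = stats, ident
        if groups is not None:
            gs = group_summaries(table, groups)
            pd.DataFrame([g.__dict__ for g in gs]).to_csv(
                out / "group_summaries.csv", index=False
            )
            bundle["group_summaries"] = gs
        _end("diversity", t0)

        t0 = _begin("distances")
        D = combined_matrix(table, model=FillModel(config.fill_model))
        D.to_csv(out / "distance_combined.csv")
        N = nei_distance_matrix(table)
        N.to_csv(out / "distance_nei.csv")
        bundle["combined"], bundle["nei"] = D, N
        _end("distances", t0)

        t0 = _begin("tree")
        tree = bootstrap_support(
            table,
            n_reps=config.bootstrap_reps,
            seed=config.seed,
            threshold_pct=config.bootstrap_threshold_pct,
        )
        tree.write_newick(out / "upgma.nwk")
        bundle["tree"] = tree
        _end("tree", t0, n_reps=config.bootstrap_reps)

        t0 = _begin("msn")
        net = minimum_spanning_network(D, include_ties=True)
        net.to_edge_csv(out / "msn_edges.csv")
        net.to_graphml(out / "msn.graphml")
        bundle["network"] = net
        _end("msn", t0, n_edges=len(net.edges()))

        t0 = _begin("pcoa")
        ord_res = pcoa(D)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=list(ord_res.ids),
            columns=[f"axis{i + 1}" for i in range(ord_res.n_axes)],
        )
        coords.to_csv(out / "pcoa_coordinates.csv", index_label="accession")
        pd.DataFrame(
            {
                "eigenvalue": ord_res.eigenvalues,
                "pct_variance": list(ord_res.pct_variance)
                + [np.nan] * (len(ord_res.eigenvalues) - len(ord_res.pct_variance)),
            }
        ).to_csv(out / "pcoa_eigen.csv", index_label="axis")
        bundle["pcoa"] = ord_res
        _end("pcoa", t0)

        if groups is not None:
            t0 = _begin("permutation_tests")
            labels, gm = group_mean_distances(D, groups)
            pd.DataFrame(gm, index=list(labels), columns=list(labels)).to_csv(
                out / "group_mean_distances.csv", index_label="group"
            )
            tests = permutation_tests(
                D, groups, n_perm=config.n_permutations, seed=config.seed
            )
            pd.DataFrame(
                [
                    {
                        "group_a": t.group_a,
                        "group_b": t.group_b,
                        "mean_distance": t.mean_distance,
                        "p": t.p_value,
                        "stars": t.stars,
                    }
                    for t in tests
                ]
            ).to_csv(out / "permutation_tests.csv", index=False)
            bundle["tests"] = tests
            _end("permutation_tests", t0, n_perm=config.n_permutations)
        else:
            log.info("no group assignment: skipping group stages")

        if config.runs:
            t0 = _begin("evanno")
            runs = LikelihoodTable.from_csv(config.runs)
            res = evanno(runs)
            res.to_dataframe().to_csv(out / "evanno.csv", index=False)
            with open(out / "evanno_summary.json", "w") as fh:
                json.dump(
                    {
                        "optimal_K_deltaK": res.optimal_K_deltaK,
                        "plateau_K": res.plateau_K,
                    },
                    fh,
                    indent=2,
                )
            bundle["evanno"] = res
            _end("evanno", t0)
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest["total_seconds"] = round(time.time() - t_total, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
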