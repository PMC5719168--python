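"""Synthetic fixtures emulating the study's sampling design.

Everything the pipeline consumes can be generated here with a seed: whole
pseudo-observed mtDNA datasets (PODs) under any of the five demographic
models with the six-culture design (9 GAC + 56 comparative samples by
default), toy genotype matrices for the f3 module produced by binomial
drift down a small population tree, and a suite of degenerate edge-case
inputs for error-path testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .coalsim import Alignment, MutationParams, mutate, simulate_genealogy, write_fasta
from .config import default_config, merge_config
from .demography import (
    DemographicModel,
    ParameterDraw,
    PriorSpec,
    build_model,
    point_mass_priors,
    sample_parameters,
)
from .f3 import GenotypeMatrix, write_genotypes


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Population roster: (name, region, n_samples, age_bp) per culture."""

    roster: tuple[tuple[str, str, int, float], ...]

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "StudyDesign":
        return cls(
            roster=tuple(
                (p["name"], p["region"], int(p["n"]), float(p["age_bp"]))
                for p in cfg["populations"]
            )
        )

    @classmethod
    def default(cls) -> "StudyDesign":
        return cls.from_config(default_config())

    @property
    def n_total(self) -> int:
        return sum(n for _, _, n, _ in self.roster)

    def n_samples(self, name: str) -> int:
        for nm, _, n, _ in self.roster:
            if nm == name:
                return n
        raise SyntheticDataError(f"no population {name!r} in design")

    def to_config(self, base: Mapping[str, Any] | None = None) -> dict[str, Any]:
        cfg = merge_config(base if base is not None else default_config(), {})
        cfg["populations"] = [
            {"name": nm, "region": rg, "n": n, "age_bp": age}
            for nm, rg, n, age in self.roster
        ]
        return cfg


def generate_pod(
    model_name: str,
    params: Mapping[str, float] | PriorSpec,
    design: StudyDesign,
    seed: int,
    config: Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Alignment, ParameterDraw]:
    """One pseudo-observed dataset under the given model and design.

    ``params`` is either a full parameter mapping (fixed truth) or a
    PriorSpec to draw the truth from.  With ``out_dir`` set, the FASTA, a
    metadata TSV (id, population, region, age_bp) and a JSON manifest are
    written alongside the returned objects.
    """
    cfg = design.to_config(config)
    model = build_model(model_name, cfg)
    if isinstance(params, PriorSpec):
        priors = params
    else:
        priors = point_mass_priors(params)
    ss = np.random.SeedSequence(seed)
    s_draw, s_tree, s_mut = ss.spawn(3)
    draw = sample_parameters(model, priors, np.random.default_rng(s_draw))
    tree = simulate_genealogy(model, draw, np.random.default_rng(s_tree))
    locus = cfg["locus"]
    mp = MutationParams(
        locus_length=int(locus["length"]),
        mu_per_site=draw["mu"],
        ts_tv_ratio=float(locus["kappa"]),
        base_frequencies=tuple(locus["base_frequencies"]),
    )
    aln = mutate(tree, mp, np.random.default_rng(s_mut))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(aln, out / "pod.fasta")
        region_of = {nm: rg for nm, rg, _, _ in design.roster}
        age_of = {nm: age for nm, _, _, age in design.roster}
        meta = pd.DataFrame(
            {
                "id": list(aln.ids),
                "population": [aln.populations[i] for i in aln.ids],
            }
        )
        meta["region"] = meta["population"].map(region_of)
        meta["age_bp"] = meta["population"].map(age_of)
        meta.to_csv(out / "pod_metadata.tsv", sep="\t", index=False)
        manifest = {
            "model": model_name,
            "seed": seed,
            "parameters": draw.as_dict(),
            "n_samples": aln.n_samples,
        }
        (out / "pod_manifest.json").write_text(json.dumps(manifest, indent=2))
    return aln, draw


def generate_toy_genotypes(
    n_pops: int,
    n_ind_per_pop: int,
    n_sites: int,
    drift_spec: Mapping[str, Any] | None,
    seed: int,
    pseudo_haploid: bool = False,
    out_prefix: str | Path | None = None,
    return_frequencies: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Toy biallelic genotypes by binomial drift down a population tree.

    Ancestral alternate-allele frequencies are uniform on (0.05, 0.95);
    each branch applies ``steps`` rounds of Wright-Fisher binomial
    resampling in a population of ``2N`` allele copies.  ``drift_spec``::

        {"nodes": [
            {"name": "anc",  "parent": None},
            {"name": "pop0", "parent": "anc", "steps": 5, "N": 100},
            ...
        ]}

    Leaves named ``pop0..pop{n_pops-1}`` are sampled (``n_ind_per_pop``
    diploid or pseudo-haploid individuals each).  ``drift_spec=None`` uses
    a star tree with 5 drift steps at N=500 per population.  With
    ``return_frequencies=True`` the true per-node allele frequencies
    (including the ancestral node) are returned alongside the matrix, for
    oracle tests against the known generating process.
    """
    if n_sites < 1:
        raise SyntheticDataError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    pop_names = [f"pop{i}" for i in range(n_pops)]
    if drift_spec is None:
        nodes = [{"name": "anc", "parent": None}] + [
            {"name": p, "parent": "anc", "steps": 5, "N": 500} for p in pop_names
        ]
    else:
        nodes = list(drift_spec["nodes"])
    by_name = {n["name"]: n for n in nodes}
    for p in pop_names:
        if p not in by_name:
            raise SyntheticDataError(f"drift_spec lacks a node for {p!r}")
    roots = [n for n in nodes if n.get("parent") is None]
    if len(roots) != 1:
        raise SyntheticDataError("drift_spec must have exactly one root")

    anc = rng.uniform(0.05, 0.95, size=n_sites)
    freqs: dict[str, np.ndarray] = {roots[0]["name"]: anc}
    remaining = [n for n in nodes if n.get("parent") is not None]
    # resolve parents iteratively (tree given in any order)
    while remaining:
        progressed = False
        for n in list(remaining):
            if n["parent"] in freqs:
                p = freqs[n["parent"]].copy()
                copies = 2 * int(n.get("N", 500))
                for _ in range(int(n.get("steps", 0))):
                    p = rng.binomial(copies, p) / copies
                freqs[n["name"]] = p
                remaining.remove(n)
                progressed = True
        if not progressed:
            raise SyntheticDataError("drift_spec tree has unresolvable parents")

    n_ind = n_pops * n_ind_per_pop
    calls = np.empty((n_sites, n_ind), dtype=np.int8)
    for k, p in enumerate(pop_names):
        f = freqs[p]
        cols = slice(k * n_ind_per_pop, (k + 1) * n_ind_per_pop)
        if pseudo_haploid:
            draw = rng.random((n_sites, n_ind_per_pop)) < f[:, None]
            calls[:, cols] = 2 * draw.astype(np.int8)
        else:
            calls[:, cols] = rng.binomial(2, f[:, None]).astype(np.int8)

    snp = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_sites)],
            "chrom": "1",
            "gen_pos": 0.0,
            "pos": np.arange(1, n_sites + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    ind = pd.DataFrame(
        {
            "id": [f"{p}_{j}" for p in pop_names for j in range(n_ind_per_pop)],
            "sex": "U",
            "population": [p for p in pop_names for _ in range(n_ind_per_pop)],
        }
    )
    G = GenotypeMatrix(
        snp=snp,
        calls=calls,
        ind=ind,
        pseudo_haploid=np.full(n_ind, pseudo_haploid),
    )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_genotypes(
            G,
            prefix.with_suffix(".geno"),
            prefix.with_suffix(".snp"),
            prefix.with_suffix(".ind"),
        )
        manifest = {
            "seed": seed,
            "n_pops": n_pops,
            "n_ind_per_pop": n_ind_per_pop,
            "n_sites": n_sites,
            "pseudo_haploid": pseudo_haploid,
        }
        prefix.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    if return_frequencies:
        return G, freqs
    return G


def make_edge_fixtures() -> dict[str, Any]:
    """Degenerate inputs paired with their expected null/error behaviour.

    Keys:
      ``monomorphic_alignment``  two-population alignment with no variation
                                 (S=0 path; Tajima's D undefined)
      ``single_sequence_population``  alignment where one population has a
                                 lone sequence (diversity stats undefined)
      ``all_missing_site``       genotype matrix whose second site is
                                 entirely missing in pop1 (site skipped in f3)
      ``single_block_jackknife`` (values, positions) spanning one block only
                                 (block jackknife must raise)
    """
    mono = Alignment.from_sequences(
        {f"a{i}": "ACGTACGTAC" for i in range(3)}
        | {f"b{i}": "ACGTACGTAC" for i in range(3)},
        {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)},
    )
    single = Alignment.from_sequences(
        {"a0": "ACGTACGTAC", "a1": "ACGTACGTAG", "b0": "ACGTACGTCC"},
        {"a0": "A", "a1": "A", "b0": "B"},
    )
    snp = pd.DataFrame(
        {
            "snp_id": ["rs0", "rs1", "rs2"],
            "chrom": "1",
            "gen_pos": 0.0,
            "pos": [1000, 2000, 3000],
            "ref": "A",
            "alt": "G",
        }
    )
    ind = pd.DataFrame(
        {
            "id": ["x0", "x1", "y0", "o0"],
            "sex": "U",
            "population": ["pop0", "pop0", "pop1", "out"],
        }
    )
    calls = np.array(
        [
            [0, 1, 2, 0],
            [1, 2, -1, 2],  # pop1 entirely missing here
            [2, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    gmat = GenotypeMatrix(snp=snp, calls=calls, ind=ind)
    one_block = (
        np.array([0.1, 0.2, 0.3]),
        pd.DataFrame({"chrom": ["1", "1", "1"], "pos": [1000, 2000, 3000]}),
    )
    return {
        "monomorphic_alignment": mono,
        "single_sequence_population": single,
        "all_missing_site": gmat,
        "single_block_jackknife": one_block,
    }
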