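"""End-to-end orchestration: from aligned sequences (or a count table) to
the full set of result tables.

Stage order mirrors the standard cpDNA phylogeography workflow: read →
drop indels → collapse haplotypes → diversity table → step matrix →
minimum spanning network → nesting + Dc/Dn + contingency + inference →
FST/Nm → isolation by distance → NJ + bootstrap → skyline. Count-only mode
(no sequences) runs the subset computable from haplotype frequencies, so a
published count table is a first-class input.

Every stochastic stage consumes an independent child seed derived from the
master seed and a fixed per-stage counter (``SeedSequence([master, k])``),
so runs are byte-identical under a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography, diversity, haplonet, phylogeny, popstruct, seqio
from .nca import (
    build_nesting,
    clade_composition_table,
    infer_all,
    nested_contingency_test,
    permutation_significance,
)

# fixed stage counters for child-seed derivation
_STAGE_SEEDS = {"nca_perm": 1, "contingency": 2, "bootstrap": 3, "ibd": 4}


def child_seed(master: int, stage: str) -> int:
    """Derive the per-stage seed: SeedSequence([master, stage_counter])."""
    k = _STAGE_SEEDS[stage]
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    outdir: str
    seed: int
    fasta: str | None = None
    popmap: str | None = None
    counts: str | None = None
    clades: str | None = None  # optional fixed nesting design (TSV)
    n_perm: int = 10000
    n_bootstrap: int = 1000
    mutation_rate: float = 3e-9
    generation_time: float | None = None
    counts_only: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fasta is None and self.counts is None:
            raise ValueError("either a FASTA alignment or a count table is required")
        if self.counts_only and self.counts is None:
            raise ValueError("counts_only mode requires a count table")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all applicable stages, writing one TSV (or newick) per output.

    Returns a bundle dict holding the in-memory results plus the output
    paths; stage failures raise :class:`StageError` naming the stage, with
    earlier outputs left on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    log: dict = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_bootstrap": cfg.n_bootstrap,
        "mutation_rate": cfg.mutation_rate,
        "generation_time": cfg.generation_time,
        "counts_only": cfg.counts_only,
        "child_seeds": {
            stage: child_seed(cfg.seed, stage) for stage in _STAGE_SEEDS
        },
        "stages": [],
    }

    def stage(name):
        log["stages"].append(name)

    table = None
    aln = None
    pmap = None
    try:
        stage("read")
        if cfg.counts is not None:
            table = seqio.read_haplotype_counts(cfg.counts)
        if cfg.popmap is not None:
            pmap = seqio.read_population_map(cfg.popmap)
        if cfg.fasta is not None and not cfg.counts_only:
            aln = seqio.read_fasta_alignment(cfg.fasta)
    except Exception as exc:
        raise StageError("read", exc)

    if aln is not None:
        try:
            stage("drop_indels")
            aln, kept = seqio.drop_indel_columns(aln)
            log["kept_columns"] = len(kept)
            stage("collapse")
            if pmap is None:
                raise ValueError("sequence mode requires a population map")
            table = seqio.collapse_haplotypes(aln, pmap)
            seqio.write_haplotype_counts(table, outdir / "haplotypes.tsv")
            with open(outdir / "haplotype_sequences.fasta", "w") as fh:
                for h in table.haplotype_ids:
                    fh.write(f">{h}\n{table.sequences[h]}\n")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("collapse", exc)

    try:
        stage("diversity")
        div = diversity.population_summary(table, aln, pmap)
        div.to_csv(outdir / "diversity.tsv", sep="\t")
        bundle["diversity"] = div
    except Exception as exc:
        raise StageError("diversity", exc)

    network = None
    design = None
    if table.sequences is None and cfg.clades is not None:
        # count-only mode with a fixed published nesting design: the
        # composition table is computable from frequencies alone
        try:
            stage("nca")
            from .nca.nesting import read_clade_memberships

            design = read_clade_memberships(cfg.clades)
            comp = clade_composition_table(design, table)
            comp.to_csv(outdir / "clade_composition.tsv", sep="\t")
            bundle["composition"] = comp
        except Exception as exc:
            raise StageError("nca", exc)
    if table.sequences is not None:
        try:
            stage("network")
            steps = haplonet.step_matrix(table)
            steps.to_csv(outdir / "step_matrix.tsv", sep="\t")
            network = haplonet.minimum_spanning_network(steps, table.counts)
            haplonet.export_network(network, outdir / "network.tsv")
            bundle["network"] = network
        except Exception as exc:
            raise StageError("network", exc)
        try:
            stage("nca")
            design = build_nesting(network)
            comp = clade_composition_table(design, table)
            comp.to_csv(outdir / "clade_composition.tsv", sep="\t")
            bundle["composition"] = comp
            if pmap is not None and pmap.pop_to_site:
                stats, contrasts = permutation_significance(
                    design, table, pmap,
                    n_perm=cfg.n_perm,
                    seed=child_seed(cfg.seed, "nca_perm"),
                    network=network,
                )
                _write_geostats(stats, contrasts, outdir)
                conting = nested_contingency_test(
                    design, table, pmap,
                    n_perm=cfg.n_perm,
                    seed=child_seed(cfg.seed, "contingency"),
                )
                pd.DataFrame(
                    [
                        {
                            "nesting_clade": r.nesting_clade_id,
                            "chi_square": r.chi_square,
                            "p_perm": r.p_perm,
                            "applicable": r.applicable,
                        }
                        for r in conting.values()
                    ]
                ).to_csv(outdir / "contingency.tsv", sep="\t", index=False)
                outcomes = infer_all(
                    design, stats, contrasts, conting, table, network,
                    alpha=cfg.alpha,
                )
                with open(outdir / "inference.tsv", "w") as fh:
                    fh.write("nesting_clade\tkey_path\tconclusion\n")
                    for cid in sorted(outcomes):
                        o = outcomes[cid]
                        path = "-".join(f"{s}{a[0]}" for s, a in o.key_path)
                        fh.write(f"{cid}\t{path}\t{o.conclusion}\n")
                bundle["nca"] = {
                    "design": design,
                    "stats": stats,
                    "contrasts": contrasts,
                    "contingency": conting,
                    "outcomes": outcomes,
                }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("nca", exc)

    if aln is not None and pmap is not None and pmap.pop_to_site:
        try:
            stage("fst")
            fm = popstruct.fst_nm_matrices(aln, pmap)
            popstruct.combined_table(fm).to_csv(outdir / "fst_nm.tsv", sep="\t")
            bundle["fst_nm"] = fm
            stage("ibd")
            ibd = popstruct.ibd_test(
                fm, pmap, n_perm=cfg.n_perm, seed=child_seed(cfg.seed, "ibd")
            )
            pd.DataFrame([ibd.__dict__]).to_csv(
                outdir / "ibd.tsv", sep="\t", index=False
            )
            bundle["ibd"] = ibd
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fst", exc)

    if table.sequences is not None and len(table.haplotype_ids) >= 3:
        try:
            stage("tree")
            hap_aln = seqio.SequenceAlignment(
                [(h, table.sequences[h]) for h in table.haplotype_ids]
            )
            tree, report = phylogeny.bootstrap_support(
                hap_aln,
                n_reps=cfg.n_bootstrap,
                seed=child_seed(cfg.seed, "bootstrap"),
            )
            phylogeny.write_newick(tree, outdir / "tree.nwk")
            bundle["tree"] = tree
            bundle["bootstrap_report"] = report
            stage("skyline")
            ultra = demography.ultrametricize_tree(tree)
            ci = demography.coalescent_intervals(ultra, rel_tol=1e-6)
            sky = demography.classic_skyline(
                ci,
                mutation_rate=cfg.mutation_rate,
                L=len(next(iter(table.sequences.values()))),
                generation_time=cfg.generation_time,
            )
            demography.skyline_table(sky).to_csv(
                outdir / "skyline.tsv", sep="\t", index=False
            )
            bundle["skyline"] = sky
        except StageError:
            raise
        except Exception as exc:
            raise StageError("tree", exc)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    bundle["log"] = log
    return bundle


def _write_geostats(stats, contrasts, outdir: Path) -> None:
    pd.DataFrame(
        [
            {
                "unit": s.clade_id,
                "status": s.status,
                "Dc_km": s.Dc,
                "Dn_km": s.Dn,
                "p_small_Dc": s.p_small_Dc,
                "p_large_Dc": s.p_large_Dc,
                "p_small_Dn": s.p_small_Dn,
                "p_large_Dn": s.p_large_Dn,
            }
            for s in stats.values()
        ]
    ).to_csv(outdir / "clade_distances.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "nesting_clade": c.nesting_clade_id,
                "it_Dc": c.it_Dc,
                "it_Dn": c.it_Dn,
                "p_small_it_Dc": c.p_small_it_Dc,
                "p_large_it_Dc": c.p_large_it_Dc,
                "p_small_it_Dn": c.p_small_it_Dn,
                "p_large_it_Dn": c.p_large_it_Dn,
            }
            for c in contrasts.values()
        ]
    ).to_csv(outdir / "interior_tip.tsv", sep="\t", index=False)


def validate_against_fixture(bundle: dict, fixture, h_tol: float = 5e-4) -> dict:
    """Compare a pipeline bundle against the packaged reference dataset.

    Recomputes haplotype diversity per population and clade composition
    directly from the fixture's counts and memberships and reports per-cell
    deltas; ``ok`` is True when every delta is within tolerance. Missing
    tables raise ``KeyError``.
    """
    div = bundle["diversity"]
    counts = fixture.haplotype_counts
    rows = []
    ok = True
    for pop in counts.populations:
        c = counts.counts[pop].to_numpy()
        c = c[c > 0]
        expected = diversity.haplotype_diversity(c) if c.sum() >= 2 else None
        got = div.loc[pop, "h"] if pop in div.index else None
        delta = (
            abs(got - expected)
            if got is not None and expected is not None and not pd.isna(got)
            else None
        )
        good = delta is not None and delta <= h_tol
        ok = ok and good
        rows.append(
            {"cell": f"h[{pop}]", "expected": expected, "got": got,
             "delta": delta, "ok": good}
        )
    pooled = counts.pooled_counts()
    expected = diversity.haplotype_diversity(pooled)
    got = div.loc["Overall", "h"]
    delta = abs(got - expected)
    rows.append(
        {"cell": "h[Overall]", "expected": expected, "got": got,
         "delta": delta, "ok": delta <= h_tol}
    )
    ok = ok and delta <= h_tol

    if "composition" in bundle:
        comp = bundle["composition"]
        ref_comp = clade_composition_table(fixture.clade_memberships, counts)
        for cid in ref_comp.index:
            if cid not in comp.index:
                rows.append({"cell": f"n[{cid}]", "expected": int(ref_comp.loc[cid, "n"]),
                             "got": None, "delta": None, "ok": False})
                ok = False
                continue
            exp_n, got_n = int(ref_comp.loc[cid, "n"]), int(comp.loc[cid, "n"])
            good = exp_n == got_n
            ok = ok and good
            rows.append({"cell": f"n[{cid}]", "expected": exp_n, "got": got_n,
                         "delta": abs(exp_n - got_n), "ok": good})
    return {"ok": ok, "report": pd.DataFrame(rows)}
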