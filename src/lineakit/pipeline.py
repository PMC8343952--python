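"""End-to-end orchestration: simulate → match → contrast → haplogroup → phylo → CMH.

``run_pipeline`` executes the full multi-evidence analysis on synthetic
two-population data (or user-supplied tables) and writes one canonical JSON
case report plus CSV side-car tables.  Stage failures for one query are
collected in an error section and never abort the other queries.  All
randomness flows from the single config seed; reports contain no timestamps,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .haplogroups import HaplogroupTree, assign_haplogroup, frequency_profile_table
from .matching import HaplotypeDB, contrast_table
from .profiles import SeqRange, build_alignment_rows, parse_range_spec, write_profile_table
from .phylo import (
    Alignment,
    bionj_tree,
    build_distance_matrix,
    clade_label_report,
    nj_tree,
    select_topology,
    write_newick,
)
from .simulate import (
    SyntheticSpec,
    default_spec,
    generate_case_set,
    generate_mt_population,
    generate_ystr_case_set,
)
from .ystr import classify_cmh, cmh_mismatch_count, cmh_report, write_ystr_table


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value)."""


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    seed: int = 0
    out_dir: str = "lineakit_run"
    population_a: str = "ashkenazi_like"
    population_b: str = "polish_like"
    query_population: str = "ashkenazi_like"
    n_queries: int = 10
    n_per_population: int = 500
    lambda_private: float = 1.0
    mu_smm: float = 0.02
    window: str = "73-340;16024-16365"
    theta: float | None = None
    kappa_init: float = 4.0
    optimize_kappa: bool = True
    phylo_refs_per_population: int = 10
    phylo_max_sweeps: int = 5
    neighbour_max: int = 3
    run_contrast: bool = True
    run_haplogroups: bool = True
    run_phylo: bool = True
    run_ystr: bool = True

    def __post_init__(self) -> None:
        if self.n_queries < 1 or self.n_per_population < 1:
            raise ConfigError("n_queries and n_per_population must be >= 1")
        if self.query_population not in (self.population_a, self.population_b):
            raise ConfigError("query_population must be one of the two populations")
        parse_range_spec(self.window)  # validates format

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def representative_records(db, truth, m: int):
    """Up to m records chosen round-robin across generating haplogroups."""
    by_group: dict[str, list] = {}
    groups_of = dict(zip(truth["sample"], truth["haplogroup"]))
    for rec in db.records:
        by_group.setdefault(groups_of[rec.sample_id], []).append(rec)
    chosen = []
    rank = 0
    while len(chosen) < m:
        added = False
        for group in sorted(by_group):
            if rank < len(by_group[group]) and len(chosen) < m:
                chosen.append(by_group[group][rank])
                added = True
        if not added:
            break
        rank += 1
    return chosen


def build_spec(config: RunConfig) -> SyntheticSpec:
    return default_spec(
        seed=config.seed,
        n_per_population=config.n_per_population,
        lambda_private=config.lambda_private,
        mu_smm=config.mu_smm,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the case report.

    Returns the report dictionary; files are written under
    ``config.out_dir``: ``report.json`` (canonical), contrast/assignment/
    frequency/CMH CSVs, the simulated reference panels (TSV), the query
    alignment (FASTA) and the selected tree (newick).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = parse_range_spec(config.window)
    spec = build_spec(config)
    tree = spec.tree

    report: dict = {
        "metadata": {
            "tool": "lineakit",
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "populations": [config.population_a, config.population_b],
            "query_population": config.query_population,
        },
        "queries": {},
        "errors": {},
    }

    # --- simulate ---------------------------------------------------------
    db_a, truth_a = generate_mt_population(spec, config.population_a)
    db_b, truth_b = generate_mt_population(spec, config.population_b)
    queries, query_truth = generate_case_set(
        spec, config.query_population, config.n_queries
    )
    write_profile_table(out / f"panel_{db_a.population}.tsv", db_a.records)
    write_profile_table(out / f"panel_{db_b.population}.tsv", db_b.records)
    write_profile_table(out / "queries.tsv", queries)
    query_truth.to_csv(out / "query_truth.csv", index=False)
    for q in queries:
        report["queries"][q.sample_id] = {}

    # --- contrast ---------------------------------------------------------
    if config.run_contrast:
        try:
            contrasts = contrast_table(queries, db_a, db_b, window)
            contrasts.to_csv(out / "contrast.csv", index=False)
            for _, row in contrasts.iterrows():
                report["queries"][row["query_id"]]["contrast"] = {
                    "x_a": int(row["x_a"]), "n_a": int(row["n_a"]),
                    "x_b": int(row["x_b"]), "n_b": int(row["n_b"]),
                    "p_a": float(row["p_a"]), "p_b": float(row["p_b"]),
                    "lr": float(row["lr"]), "winner": row["winner"],
                }
        except Exception as err:  # stage-level failure, report and continue
            report["errors"]["contrast"] = str(err)
    else:
        for q in queries:
            report["queries"][q.sample_id]["contrast"] = "skipped"

    # --- haplogrouping ----------------------------------------------------
    groups = sorted(
        set(spec.mt_frequencies[config.population_a])
        | set(spec.mt_frequencies[config.population_b])
    )
    if config.run_haplogroups:
        for q in queries:
            try:
                a = assign_haplogroup(q, tree)
                report["queries"][q.sample_id]["haplogroup"] = {
                    "best": a.best, "score": a.score, "matched": a.matched,
                    "missing": a.missing, "private": a.private,
                }
            except Exception as err:
                report["errors"][q.sample_id] = f"haplogroup: {err}"
        try:
            freq = frequency_profile_table([db_a, db_b], tree, groups)
            freq.to_csv(out / "haplogroup_frequencies.csv")
            report["haplogroup_frequencies"] = {
                pop: {g: float(v) for g, v in row.items()}
                for pop, row in freq.iterrows()
            }
        except Exception as err:
            report["errors"]["haplogroup_frequencies"] = str(err)
    else:
        for q in queries:
            report["queries"][q.sample_id]["haplogroup"] = "skipped"

    # --- phylogeography ---------------------------------------------------
    if config.run_phylo:
        try:
            m = config.phylo_refs_per_population
            # representative mitotypes: round-robin over assigned haplogroups,
            # so every clade present in a panel is in the tree
            refs_a = representative_records(db_a, truth_a, m)
            refs_b = representative_records(db_b, truth_b, m)
            refs = refs_a + refs_b
            labels = {r.sample_id: db_a.population for r in refs_a}
            labels.update({r.sample_id: db_b.population for r in refs_b})
            labels.update({q.sample_id: "case" for q in queries})
            rows = build_alignment_rows(refs + queries, spec.reference, window)
            aln = Alignment([r[0] for r in rows], [r[1] for r in rows], labels)
            aln.to_fasta(out / "alignment.fasta")
            dm = build_distance_matrix(aln, theta=config.theta)
            fit = select_topology(
                [nj_tree(dm), bionj_tree(dm)],
                aln,
                theta=config.theta,
                kappa=config.kappa_init,
                optimize_kappa=config.optimize_kappa,
                max_sweeps=config.phylo_max_sweeps,
            )
            write_newick(fit.tree, out / "tree.nwk")
            clades = clade_label_report(
                fit.tree, labels, [q.sample_id for q in queries]
            )
            clades.to_csv(out / "clades.csv", index=False)
            report["phylo"] = {
                "loglik": fit.loglik,
                "theta": fit.params.theta,
                "kappa": fit.params.kappa,
                "n_taxa": len(aln),
            }
            for _, row in clades.iterrows():
                report["queries"][row["query"]]["clade_call"] = row["call"]
        except Exception as err:
            report["errors"]["phylo"] = str(err)
    else:
        for q in queries:
            report["queries"][q.sample_id]["clade_call"] = "skipped"

    # --- Y-STR / CMH ------------------------------------------------------
    if config.run_ystr:
        try:
            yhaps, y_truth = generate_ystr_case_set(
                spec, config.query_population, config.n_queries
            )
            write_ystr_table(out / "queries_ystr.tsv", yhaps)
            y_truth.to_csv(out / "query_ystr_truth.csv", index=False)
            table = cmh_report(yhaps, config.neighbour_max)
            table.to_csv(out / "cmh.csv", index=False)
            for h in yhaps:
                mism, compared, missing = cmh_mismatch_count(h)
                entry = report["queries"].setdefault(h.sample_id, {})
                entry["cmh"] = {
                    "class": classify_cmh(h, config.neighbour_max),
                    "mismatches": mism,
                    "compared": compared,
                    "missing": missing,
                }
        except Exception as err:
            report["errors"]["ystr"] = str(err)
    else:
        for q in queries:
            report["queries"][q.sample_id]["cmh"] = "skipped"

    _atomic_write(out / "report.json", json.dumps(report, indent=2, sort_keys=True))
    return report
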