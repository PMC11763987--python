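"""End-to-end pipeline orchestration.

Stages communicate exclusively through files under the output directory, so
any stage can be re-run in isolation and synthetic ensembles can be replaced
by real MD-derived PDB ensembles without code changes:

* ``simulate``  -> ``ensembles/<variant>.pdb`` (+ the reference peptide)
* ``extract``   -> ``feature_matrix.csv``, ``feature_matrix_imputed.csv``
* ``select``    -> ``selection_rounds.csv``, ``selection_report.csv``
* ``classify``  -> ``accuracy_table.csv``, ``loo_per_variant.csv``
* ``cluster``   -> ``clusters_<name>.csv``, ``representatives/<name>_<k>.pdb``
* ``align``     -> ``alignments.csv``, ``hit_table.csv``, ``dot_plot.csv``
* ``score``     -> ``consensus_simulation.csv``, ``consensus_combined.csv``

A machine-readable ``run_manifest.json`` records package version, seed,
parameters, per-stage wall time and output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import align_representatives, dot_plot, filter_alignments, hit_table
from .classify import DEFAULT_N_TREES, DEFAULT_SUBSETS, accuracy_table, loo_variant_cv
from .cluster import cluster_ensemble
from .consensus import (
    DEFAULT_WEIGHTS,
    ML_SOURCE,
    EvidenceSource,
    ml_residues,
    read_sequence_tiers,
    score_residues,
    split_reports,
    structural_sources,
)
from .features import (
    ANGLE_COLUMNS,
    impute_missing,
    matrix_from_ensembles,
)
from .io import read_ensemble, read_manifest, write_ensemble, write_manifest
from .selection import SelectionRound, iterate_selection, selection_report
from .synthetic import (
    Ensemble,
    EnsembleParams,
    generate_ensemble,
    generate_reference_ensemble,
)
from .variants import AMYLOID_BETA_42, VariantSpec, default_manifest

STAGES = ("simulate", "extract", "select", "classify", "cluster", "align", "score")


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    ``manifest`` may be a path to a YAML manifest or ``None`` for the default
    eight-variant design.  All stage parameters default to the reference
    settings of the analysis (3 x 1000 frames, 2 A clustering cutoff, 2 %
    retention, 2 A alignment filter, 5000-tree forests, 3 selection rounds,
    ML evidence from rounds 1-2).
    """

    outdir: str = "dihedra_out"
    manifest: str | None = None
    seed: int = 0
    n_trajectories: int = 3
    frames_per_trajectory: int = 1000
    capped: bool = True
    cluster_cutoff: float = 2.0
    retention_fraction: float = 0.02
    rmsd_max: float = 2.0
    frag_len: int = 5
    extend_cutoff: float = 3.0
    n_trees: int = DEFAULT_N_TREES
    n_rounds: int = 3
    ml_rounds: tuple[int, ...] = (1, 2)
    consensus_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    sequence_tiers: str | None = None
    cluster_target: str = "human_amylin"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ml_rounds" in doc:
            doc["ml_rounds"] = tuple(doc["ml_rounds"])
        return cls(**doc)


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Schema and range checks; warnings flag departures from the reference
    defaults."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    if config.cluster_cutoff <= 0:
        err(f"cluster cutoff must be positive, got {config.cluster_cutoff}")
    if not (0 <= config.retention_fraction <= 1):
        err(f"retention fraction must lie in [0, 1], got {config.retention_fraction}")
    if config.rmsd_max <= 0:
        err(f"alignment RMSD filter must be positive, got {config.rmsd_max}")
    if config.n_trajectories < 1 or config.frames_per_trajectory < 1:
        err("ensemble layout counts must be >= 1")
    if config.n_trees < 1:
        err("forest size must be >= 1")
    if config.n_rounds < 1:
        err("need at least one selection round")
    if config.manifest is not None and not Path(config.manifest).exists():
        err(f"manifest path does not exist: {config.manifest}")
    if config.sequence_tiers is not None and not Path(config.sequence_tiers).exists():
        err(f"sequence tiers path does not exist: {config.sequence_tiers}")

    if not findings or all(f.level == "warning" for f in findings):
        if config.n_trees != DEFAULT_N_TREES:
            warn(f"forest size {config.n_trees} differs from the reference 5000")
        if config.cluster_cutoff != 2.0:
            warn(f"cluster cutoff {config.cluster_cutoff} differs from the reference 2.0 A")
        if config.retention_fraction != 0.02:
            warn(
                f"retention fraction {config.retention_fraction} differs from the "
                "reference 0.02"
            )
        if config.rmsd_max != 2.0:
            warn(f"alignment filter {config.rmsd_max} differs from the reference 2.0 A")
    return findings


class PipelineRunner:
    """Executes pipeline stages against an output directory."""

    def __init__(self, config: PipelineConfig, verbose: bool = False):
        errors = [f for f in validate_config(config) if f.level == "error"]
        if errors:
            raise ValueError(
                "invalid configuration: " + "; ".join(f.message for f in errors)
            )
        self.config = config
        self.verbose = verbose
        self.outdir = Path(config.outdir)
        self.timings: dict[str, float] = {}

    # -- helpers ----------------------------------------------------------
    def _log(self, msg: str) -> None:
        if self.verbose:
            print(msg)

    def _specs(self) -> tuple[list[VariantSpec], dict]:
        if self.config.manifest is None:
            specs = default_manifest()
            reference = {"name": "amyloid_beta", "sequence": AMYLOID_BETA_42}
        else:
            specs, reference = read_manifest(self.config.manifest)
            if reference is None:
                reference = {"name": "amyloid_beta", "sequence": AMYLOID_BETA_42}
        return specs, reference

    def _params(self) -> EnsembleParams:
        return EnsembleParams(
            n_trajectories=self.config.n_trajectories,
            frames_per_trajectory=self.config.frames_per_trajectory,
            seed=self.config.seed,
        )

    def _matrix_path(self, imputed: bool = True) -> Path:
        name = "feature_matrix_imputed.csv" if imputed else "feature_matrix.csv"
        return self.outdir / name

    def _read_matrix(self, imputed: bool = True) -> pd.DataFrame:
        path = self._matrix_path(imputed)
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found; run the extract stage first"
            )
        df = pd.read_csv(path, index_col=[0, 1, 2])
        # the variant column shares its name with an index level; pandas
        # mangles the duplicate header on read
        df = df.rename(columns={"variant.1": "variant"})
        return df

    def _read_rounds(self) -> list[SelectionRound]:
        raise NotImplementedError  # rounds are reloaded as angle lists, below

    def _read_round_angles(self) -> dict[int, tuple[str, ...]]:
        path = self.outdir / "selection_rounds.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found; run the select stage first")
        df = pd.read_csv(path)
        out: dict[int, tuple[str, ...]] = {}
        for rnd, grp in df.groupby("round"):
            out[int(rnd)] = tuple(grp.sort_values("order")["angle"])
        return out

    # -- stages -----------------------------------------------------------
    def simulate(self) -> None:
        specs, reference = self._specs()
        params = self._params()
        ens_dir = self.outdir / "ensembles"
        ens_dir.mkdir(parents=True, exist_ok=True)
        for spec in specs:
            ens = generate_ensemble(spec, params, capped=self.config.capped)
            write_ensemble(ens, ens_dir / f"{spec.name}.pdb")
            self._log(f"simulate: wrote {spec.name} ({len(ens)} models)")
        ref = generate_reference_ensemble(
            reference["name"], reference["sequence"], params, capped=self.config.capped
        )
        write_ensemble(ref, ens_dir / f"{reference['name']}.pdb")
        write_manifest(specs, self.outdir / "manifest.yaml", reference=reference)

    def extract(self) -> None:
        specs, _ = self._specs()
        ens_dir = self.outdir / "ensembles"
        ensembles: list[Ensemble] = []
        for spec in specs:
            ens = read_ensemble(ens_dir / f"{spec.name}.pdb")
            ens.class_label = spec.class_label
            ensembles.append(ens)
        matrix = matrix_from_ensembles(
            ensembles, frames_per_trajectory=self.config.frames_per_trajectory
        )
        matrix.to_csv(self._matrix_path(imputed=False))
        impute_missing(matrix).to_csv(self._matrix_path(imputed=True))

    def select(self) -> None:
        matrix = self._read_matrix()
        rounds = iterate_selection(
            matrix, n_rounds=self.config.n_rounds, seed=self.config.seed
        )
        rows = [
            {"round": r.round_index, "order": i, "angle": angle}
            for r in rounds
            for i, angle in enumerate(r.selected_angles)
        ]
        pd.DataFrame(rows, columns=["round", "order", "angle"]).to_csv(
            self.outdir / "selection_rounds.csv", index=False
        )
        selection_report(rounds).to_csv(self.outdir / "selection_report.csv", index=False)

    def classify(self) -> None:
        matrix = self._read_matrix()
        round_angles = self._read_round_angles()
        rounds = [
            _AngleOnlyRound(idx, angles) for idx, angles in sorted(round_angles.items())
        ]
        table = accuracy_table(
            matrix,
            rounds,  # type: ignore[arg-type]  # duck-typed: only .round_index/.selected_angles used
            subsets=DEFAULT_SUBSETS,
            n_trees=self.config.n_trees,
            seed=self.config.seed,
        )
        table.to_csv(self.outdir / "accuracy_table.csv", index=False)
        ml_feats = tuple(
            dict.fromkeys(
                a
                for idx in self.config.ml_rounds
                for a in round_angles.get(idx, ())
            )
        )
        if ml_feats:
            loo = loo_variant_cv(
                matrix, ml_feats, n_trees=self.config.n_trees, seed=self.config.seed
            )
            loo.per_variant.to_csv(self.outdir / "loo_per_variant.csv")

    def cluster(self) -> None:
        specs, reference = self._specs()
        ens_dir = self.outdir / "ensembles"
        reps_dir = self.outdir / "representatives"
        reps_dir.mkdir(parents=True, exist_ok=True)
        for name in (self.config.cluster_target, reference["name"]):
            ens = read_ensemble(ens_dir / f"{name}.pdb")
            cs = cluster_ensemble(
                ens,
                cutoff=self.config.cluster_cutoff,
                min_fraction=self.config.retention_fraction,
            )
            cs.table().to_csv(self.outdir / f"clusters_{name}.csv", index=False)
            for k, rep in enumerate(cs.representatives(retained_only=True)):
                single = Ensemble(
                    name=ens.name,
                    sequence=ens.sequence,
                    positions=ens.positions,
                    conformations=[ens.conformations[rep]],
                )
                write_ensemble(single, reps_dir / f"{name}_{k}.pdb")
            self._log(
                f"cluster: {name}: {len(cs.clusters)} clusters, "
                f"{sum(cs.retained or [])} retained"
            )

    def align(self) -> None:
        specs, reference = self._specs()
        reps_dir = self.outdir / "representatives"
        a_reps = sorted(reps_dir.glob(f"{self.config.cluster_target}_*.pdb"))
        b_reps = sorted(reps_dir.glob(f"{reference['name']}_*.pdb"))
        if not a_reps or not b_reps:
            raise FileNotFoundError(
                "no representatives found; run the cluster stage first"
            )
        confs_a = [read_ensemble(p).conformations[0] for p in a_reps]
        confs_b = [read_ensemble(p).conformations[0] for p in b_reps]
        n_a = confs_a[0].n_residues
        n_b = confs_b[0].n_residues
        alignments = align_representatives(
            confs_a,
            confs_b,
            frag_len=self.config.frag_len,
            extend_cutoff=self.config.extend_cutoff,
        )
        retained = filter_alignments(alignments, rmsd_max=self.config.rmsd_max)
        retained_ids = {a.pair_id for a in retained}
        pd.DataFrame(
            [
                {
                    "pair_id": a.pair_id,
                    "n_aligned": len(a),
                    "rmsd": a.rmsd,
                    "retained": a.pair_id in retained_ids,
                }
                for a in alignments
            ]
        ).to_csv(self.outdir / "alignments.csv", index=False)
        ht = hit_table(retained, n_residues=n_a)
        ht.table().to_csv(self.outdir / "hit_table.csv")
        dot_plot(retained, n_a=n_a, n_b=n_b).to_csv(self.outdir / "dot_plot.csv")

    def score(self) -> None:
        round_angles = self._read_round_angles()
        rounds = [
            _AngleOnlyRound(idx, angles) for idx, angles in sorted(round_angles.items())
        ]
        weights = self.config.consensus_weights
        sources = [
            EvidenceSource(
                ML_SOURCE,
                ml_residues(rounds, use_rounds=self.config.ml_rounds),  # type: ignore[arg-type]
                weights[ML_SOURCE],
            )
        ]
        hit_path = self.outdir / "hit_table.csv"
        if hit_path.exists():
            ht_df = pd.read_csv(hit_path, index_col=0)
            from .align import HitTable

            hits = ht_df["hits"].to_numpy()
            ht = HitTable(
                hits=hits,
                mean=float(hits.mean()),
                sd=float(hits.std(ddof=0)),
                n_alignments=int(hits.max()) if len(hits) else 0,
            )
            sources.extend(structural_sources(ht, weights))
        if self.config.sequence_tiers is not None:
            sources.extend(read_sequence_tiers(self.config.sequence_tiers, weights))
        table = score_residues(sources)
        report_a, report_b = split_reports(table, sources)
        report_a.to_csv(self.outdir / "consensus_simulation.csv")
        report_b.to_csv(self.outdir / "consensus_combined.csv")

    # -- orchestration ----------------------------------------------------
    def run(self, stages: tuple[str, ...] = STAGES) -> None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            try:
                getattr(self, stage)()
            except Exception as err:
                raise RuntimeError(f"stage {stage!r} failed: {err}") from err
            self.timings[stage] = time.time() - t0
            self._log(f"{stage}: done in {self.timings[stage]:.1f} s")
        self._write_run_manifest(stages)

    def run_all(self) -> None:
        self.run(STAGES)

    def _write_run_manifest(self, stages: tuple[str, ...]) -> None:
        digests = {}
        for path in sorted(self.outdir.rglob("*.csv")):
            digests[str(path.relative_to(self.outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
        manifest = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "stages": list(stages),
            "wall_time_s": self.timings,
            "output_digests": digests,
        }
        with open(self.outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


class _AngleOnlyRound:
    """Lightweight stand-in for a SelectionRound reloaded from disk (only the
    round index and the selected angles survive the CSV round trip)."""

    def __init__(self, round_index: int, selected_angles: tuple[str, ...]):
        self.round_index = round_index
        self.selected_angles = selected_angles
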