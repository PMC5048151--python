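"""Configuration-driven orchestration of the analysis stages.

A run executes, in order: generate -> morpho -> mra -> gma -> barcode,
each stage writing its tables to the output directory, and finishes with
a machine-readable ``summary.json``.  Identical configurations produce
byte-identical summaries.
"""
from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import barcode as bc
from . import datagen, gma, morphostats, mra
from .errors import CryptaxError, ValidationError
from .measurements import read_measurements, write_measurements

logger = logging.getLogger(__name__)

STAGES = ("generate", "morpho", "mra", "gma", "barcode")


class StageError(CryptaxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    scenario: dict | None = None          # {"seed": int, "n_per_species": int}
    inputs: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    n_boot: int = 200
    n_perm: int = 199
    n_reps: int = 200
    metric: str = "k2p"
    noise_sd: float = 0.02
    tol: float = 1e-10
    collapse: bool = False
    support_threshold: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stages: {unknown}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if self.scenario is None and "generate" in self.stages:
            raise ValidationError("stage 'generate' enabled but no scenario block")
        if "generate" not in self.stages:
            needs = {
                "morpho": ["measurements"],
                "mra": ["measurements", "partition"],
                "gma": ["landmarks"],
                "barcode": ["sequences"],  # partition may come from FASTA headers
            }
            for stage in self.stages:
                for key in needs.get(stage, []):
                    if key not in self.inputs:
                        raise ValidationError(
                            f"stage {stage!r} requires input {key!r} when "
                            "'generate' is disabled"
                        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = raw.pop("params", {})
        stages = raw.pop("stages", list(STAGES))
        return cls(
            scenario=raw.pop("scenario", None),
            inputs=raw.pop("inputs", {}),
            stages=tuple(stages),
            seed=raw.pop("seed", 0),
            **params,
        )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig, outdir) -> dict:
    """Execute the configured stages and write ``summary.json``.

    Returns the summary dict.  A stage failure writes a ``STALE`` marker
    naming the failed stage (earlier outputs may be incomplete) and
    re-raises as :class:`StageError`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {"seed": config.seed, "stages": list(config.stages),
                                "metric": config.metric}}
    state: dict = {}
    stage = None
    try:
        for stage in config.stages:
            _STAGE_FNS[stage](config, out, state, summary)
    except Exception as exc:
        (out / "STALE").write_text(f"failed stage: {stage}\n{exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage or "?", exc) from exc
    text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(text + "\n")
    return summary


# ---------------------------------------------------------------------------
# stages

def _stage_generate(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    scen_cfg = dict(config.scenario or {})
    scenario = datagen.default_scenario(
        seed=scen_cfg.get("seed", config.seed),
        n_per_species=scen_cfg.get("n_per_species", 12),
    )
    state["scenario"] = scenario
    measurements = datagen.gen_measurements(scenario)
    landmarks = datagen.gen_landmarks(scenario, noise_sd=config.noise_sd)
    sequences, partition = datagen.gen_sequences(scenario)
    write_measurements(measurements, out / "measurements.csv")
    gma.write_tps(landmarks, out / "landmarks.tps")
    sequences.to_fasta(out / "sequences.fasta", partition)
    bc.write_partition(partition, out / "partition.csv")
    state.update(
        measurements=measurements, landmarks=landmarks,
        sequences=sequences, partition=partition,
    )
    summary["generate"] = {
        "n_specimens": int(len(measurements)),
        "species": [m.name for m in scenario.species],
        "alignment_length": scenario.length,
        "inputs_sha256": {
            name: _file_hash(out / name)
            for name in ("measurements.csv", "landmarks.tps",
                         "sequences.fasta", "partition.csv")
        },
    }


def _measurements(config: RunConfig, state: dict):
    if "measurements" not in state:
        state["measurements"] = read_measurements(config.inputs["measurements"])
    return state["measurements"]


def _partition(config: RunConfig, state: dict):
    if "partition" not in state:
        state["partition"] = bc.read_partition(config.inputs["partition"])
    return state["partition"]


def _stage_morpho(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    table = _measurements(config, state)
    summaries = morphostats.summarize_characters(table)
    comparisons = morphostats.tukey_hsd(table, alpha=config.alpha)
    summaries.to_csv(out / "morpho_summary.csv", index=False)
    comparisons.to_csv(out / "morpho_tukey.csv", index=False)
    sig = comparisons[comparisons["significant"]]
    per_pair = {
        f"{a} vs {b}": sorted(g["character"].tolist())
        for (a, b), g in sig.groupby(["species_a", "species_b"])
    }
    summary["morpho"] = {
        "alpha": config.alpha,
        "n_significant": int(len(sig)),
        "significant_characters": per_pair,
    }


def _stage_mra(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    table = _measurements(config, state)
    space = mra.to_shape_space(table)
    fit = mra.shape_pca(space)
    spectra = [
        mra.pca_ratio_spectrum(space, 1, n_boot=config.n_boot, seed=config.seed),
        mra.pca_ratio_spectrum(space, 2, n_boot=config.n_boot, seed=config.seed + 1),
        mra.allometry_ratio_spectrum(space, n_boot=config.n_boot, seed=config.seed + 2),
    ]
    import pandas as pd

    pd.concat([s.to_frame() for s in spectra], ignore_index=True).to_csv(
        out / "mra_spectra.csv", index=False
    )
    pd.DataFrame(
        {
            "specimen_id": space.ids,
            "species": space.species,
            "isosize": space.isosize,
            "pc1": fit.scores[:, 0],
            "pc2": fit.scores[:, 1] if fit.scores.shape[1] > 1 else 0.0,
        }
    ).to_csv(out / "mra_scores.csv", index=False)

    species = sorted(set(space.species))
    comparisons = [(a, b) for a, b in itertools.combinations(species, 2)]
    comparisons += [(sp, set(species) - {sp}) for sp in species if len(species) > 2]
    lda_rows = []
    for ga, gb in comparisons:
        res = mra.lda_ratio_extract(space, group_a=ga, group_b=gb)
        lda_rows.append(
            {
                "group_a": res.group_a,
                "group_b": res.group_b,
                "best_ratio": f"{res.best.numerator}/{res.best.denominator}",
                "best_standard_distance": res.best.standard_distance,
                "best_range_a": list(res.best.range_a),
                "best_range_b": list(res.best.range_b),
                "second_ratio": f"{res.second.numerator}/{res.second.denominator}",
                "second_standard_distance": res.second.standard_distance,
                "delta": res.delta,
                "standard_distance_lda": res.standard_distance_lda,
                "separable": res.separable,
            }
        )
    (out / "mra_lda.json").write_text(json.dumps(lda_rows, indent=2, sort_keys=True) + "\n")
    summary["mra"] = {
        "percent_variance": [round(float(v), 6) for v in fit.percent_variance[:5]],
        "lda": lda_rows,
    }


def _stage_gma(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    if "landmarks" in state:
        landmarks = state["landmarks"]
    else:
        landmarks = gma.read_tps(config.inputs["landmarks"])
    fit = gma.gpa(landmarks, tol=config.tol)
    pca = gma.landmark_pca(fit)
    cva_res = gma.cva(fit)
    tests = gma.covmat_correlation_test(
        fit, n_perm=config.n_perm, seed=config.seed
    )
    import pandas as pd

    pd.DataFrame(
        {
            "specimen_id": fit.ids,
            "species": fit.species,
            "centroid_size": fit.centroid_sizes,
            "pc1": pca.scores[:, 0] if not pca.degenerate else 0.0,
            "pc2": pca.scores[:, 1] if not pca.degenerate and pca.scores.shape[1] > 1 else 0.0,
            "cv1": cva_res.scores[:, 0],
        }
    ).to_csv(out / "gma_scores.csv", index=False)
    summary["gma"] = {
        "converged": fit.converged,
        "iterations": fit.iterations,
        "percent_variance": [round(float(v), 6) for v in pca.percent_variance[:5]],
        "matrix_correlations": [
            {
                "groups": [t.group_a, t.group_b],
                "correlation": round(t.correlation, 6),
                "p_value": round(t.p_value, 6),
            }
            for t in tests
        ],
    }


def _stage_barcode(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    if "sequences" in state:
        sequences, partition = state["sequences"], _partition(config, state)
    else:
        sequences = bc.AlignedSequences.from_fasta(config.inputs["sequences"])
        if all("|" in sid for sid in sequences.ids):
            sequences, partition = bc.partition_from_headers(sequences)
        else:
            partition = _partition(config, state)
    haplotypes, multiplicity, hap_partition = bc.collapse_haplotypes(sequences, partition)
    summaries = {
        metric: bc.distance_summary(haplotypes, hap_partition, metric)
        for metric in ("k2p", "p")
    }
    summaries["k2p"].intra.to_csv(out / "barcode_intra_k2p.csv", index=False)
    summaries["k2p"].inter.to_csv(out / "barcode_inter_k2p.csv", index=False)
    summaries["p"].intra.to_csv(out / "barcode_intra_p.csv", index=False)
    summaries["p"].inter.to_csv(out / "barcode_inter_p.csv", index=False)
    gap = bc.barcode_gap(haplotypes, hap_partition, config.metric)
    boot = bc.bootstrap_support(
        sequences,
        metric=config.metric,
        n_reps=config.n_reps,
        seed=config.seed,
        partition=partition,
        collapse=config.collapse,
        support_threshold=config.support_threshold,
    )
    (out / "barcode_nj.nwk").write_text(
        boot.tree.to_newick(support_threshold=config.support_threshold) + "\n"
    )
    diagnostics = bc.pure_diagnostic_characters(sequences, partition)
    diagnostics.to_csv(out / "barcode_diagnostics.csv")

    species_clades = {}
    leaf_set = frozenset(boot.tree.leaf_names())
    for sp in bc.species_in(partition):
        members = frozenset(i for i in boot.tree.leaf_names() if partition[i] == sp)
        if 1 < len(members) < len(leaf_set) - 1:
            split = bc._canonical_split(members, leaf_set)
            species_clades[sp] = boot.supports.get(split)
    summary["barcode"] = {
        "n_haplotypes": len(haplotypes),
        "multiplicities": {k: int(v) for k, v in sorted(multiplicity.items())},
        "distance_summary": {
            metric: {
                "intra": ds.intra.round(6).to_dict(orient="records"),
                "inter": ds.inter.round(6).to_dict(orient="records"),
            }
            for metric, ds in summaries.items()
        },
        "barcode_gap": {
            "metric": gap.metric,
            "max_intra": round(gap.max_intra, 8),
            "max_intra_pair": list(gap.max_intra_pair),
            "min_inter": round(gap.min_inter, 8),
            "min_inter_pair": list(gap.min_inter_pair),
            "gap": gap.gap,
        },
        "nj_bootstrap": {
            "n_reps": boot.n_reps,
            "n_dropped": boot.n_dropped,
            "species_clade_support": {
                k: (round(v, 4) if v is not None else None)
                for k, v in sorted(species_clades.items())
            },
        },
        "diagnostics": {
            sp: {str(pos): state for pos, state in sorted(d.items())}
            for sp, d in diagnostics.pure.items()
        },
    }


_STAGE_FNS = {
    "generate": _stage_generate,
    "morpho": _stage_morpho,
    "mra": _stage_mra,
    "gma": _stage_gma,
    "barcode": _stage_barcode,
}
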