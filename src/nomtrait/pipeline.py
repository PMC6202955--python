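"""End-to-end orchestration: impute -> distances x linkages x k -> validity ->
stability -> 2-D embedding, from a single config with one master seed.

Every stage writes plain CSV/JSON/Newick artifacts into a run directory and
the run manifest records the config, derived sub-seeds, package versions and
a hash of every output, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import LINKAGES, hierarchical_cluster, pam
from .distances import MEASURES, DissimilarityMatrix, dissimilarity
from .evaluate import adjusted_rand, evaluate_cuts
from .impute import get_imputer
from .matrix import TraitMatrix, drop_high_missing_traits, read_trait_matrix
from .cluster import cut_tree

__all__ = ["PipelineConfig", "run_pipeline", "embed_2d", "pairwise_ari_table"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings of one full analysis run.

    Defaults mirror the standard study design: 25% missingness cutoff, all
    five measures, all three linkages, k in 2..10 for the validity grid and
    k in {3, 5, 7, 9} for stability.
    """

    input_csv: str | None = None
    codebook_csv: str | None = None
    out_dir: str = "run"
    missing_cutoff: float = 0.25
    imputer: str = "polytomous"
    measures: tuple = tuple(MEASURES)
    linkages: tuple = tuple(LINKAGES)
    k_grid: tuple = tuple(range(2, 11))
    stability_k: tuple = (3, 5, 7, 9)
    stability_reps: int = 100
    ari_k: tuple = (3, 9)
    embed_perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {unknown}")
        unknown = set(self.linkages) - set(LINKAGES)
        if unknown:
            raise ValueError(f"unknown linkages {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("measures", "linkages", "k_grid", "stability_k", "ari_k"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def embed_2d(
    d: DissimilarityMatrix, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """Two-dimensional stochastic-neighbor (t-SNE) embedding of a
    dissimilarity matrix, for visual inspection only.

    Perplexity is clamped below n; an all-zero matrix (no structure to embed)
    returns origin-stacked coordinates with a warning.
    """
    n = d.n
    if not np.any(d.values > 0):
        warnings.warn("degenerate all-zero dissimilarity; returning origin points")
        return np.zeros((n, 2))
    from sklearn.manifold import TSNE

    perp = float(min(perplexity, max(1.0, n - 1.000001)))
    if perp >= n:
        perp = n - 1.0
    ts = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perp,
    )
    return ts.fit_transform(d.values)


def pairwise_ari_table(partitions: dict[str, "Partition"]) -> pd.DataFrame:
    """Symmetric adjusted-Rand agreement between same-k partitions of the same
    objects, keyed by combination name (e.g. ``goodall/average``)."""
    names = list(partitions)
    ks = {p.k for p in partitions.values()}
    if len(ks) > 1:
        raise ValueError(f"partitions have mixed k: {sorted(ks)}")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            v = adjusted_rand(partitions[a], partitions[b])
            out.loc[a, b] = out.loc[b, a] = v
    return out


def _sub_seeds(master: int, labels) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {lab: int(rng.integers(2**31)) for lab in labels}


def run_pipeline(cfg: PipelineConfig, tm: TraitMatrix | None = None) -> Path:
    """Execute the full analysis; returns the run directory.

    ``tm`` may be passed directly (e.g. a synthetic matrix); otherwise the
    config's input/codebook CSVs are read.  Any stage failure aborts with a
    stage-labelled error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nomtrait")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _sub_seeds(cfg.seed, ["impute", "stability", "embed"])
    outputs: list[Path] = []

    stage = {"name": "init"}

    def _stage(name):
        stage["name"] = name
        logger.info("stage %s", name)

    try:
        _stage("load")
        if tm is None:
            if cfg.input_csv is None or cfg.codebook_csv is None:
                raise ValueError("no matrix given and no input/codebook paths in config")
            tm = read_trait_matrix(cfg.input_csv, cfg.codebook_csv)
        logger.info("loaded matrix n=%d m=%d", tm.n, tm.m)

        _stage("screen+impute")
        tm = drop_high_missing_traits(tm, cfg.missing_cutoff)
        imputer = get_imputer(cfg.imputer)
        tm_full = imputer(tm, seed=seeds["impute"])
        p = out / "imputed_matrix.csv"
        from .matrix import write_trait_matrix

        write_trait_matrix(tm_full, p)
        outputs.append(p)

        _stage("distances+clustering+evaluation")
        eval_frames = []
        partitions: dict[int, dict[str, object]] = {k: {} for k in cfg.ari_k}
        for meas in cfg.measures:
            d = dissimilarity(tm_full, meas)
            p = out / f"dissimilarity_{meas}.csv"
            d.to_frame().to_csv(p)
            outputs.append(p)
            coords = embed_2d(d, seed=seeds["embed"], perplexity=cfg.embed_perplexity)
            p = out / f"embedding_{meas}.csv"
            pd.DataFrame(coords, index=d.ids, columns=["x", "y"]).to_csv(p)
            outputs.append(p)
            for link in cfg.linkages:
                dg = hierarchical_cluster(d, link)
                p = out / f"dendrogram_{meas}_{link}.nwk"
                p.write_text(dg.to_newick() + "\n")
                outputs.append(p)
                p = out / f"merges_{meas}_{link}.csv"
                dg.to_merge_frame().to_csv(p, index=False)
                outputs.append(p)
                sub = evaluate_cuts(tm_full, dg, cfg.k_grid)
                sub.insert(0, "linkage", link)
                sub.insert(0, "measure", meas)
                eval_frames.append(sub)
                for k in cfg.ari_k:
                    if k <= tm_full.n:
                        part = cut_tree(dg, k)
                        partitions[k][f"{meas}/{link}"] = part
                        p = out / f"partition_{meas}_{link}_k{k}.csv"
                        part.to_frame().to_csv(p, index=False)
                        outputs.append(p)
        table = pd.concat(eval_frames, ignore_index=True)
        p = out / "evaluation_table.csv"
        table.to_csv(p, index=False)
        outputs.append(p)
        chosen = {
            f"{m}/{l}": int(g.loc[g["optimal"], "k"].iloc[0])
            for (m, l), g in table.groupby(["measure", "linkage"])
            if g["optimal"].any()
        }
        p = out / "selected_k.json"
        p.write_text(json.dumps(chosen, indent=2, sort_keys=True) + "\n")
        outputs.append(p)

        _stage("ari")
        for k, parts in partitions.items():
            if len(parts) >= 2:
                tab = pairwise_ari_table(parts)
                p = out / f"ari_k{k}.csv"
                tab.to_csv(p)
                outputs.append(p)

        _stage("stability")
        from .stability import bootstrap_stability

        stab_frames = []
        for meas in cfg.measures:
            for k in cfg.stability_k:
                if not 2 <= k < tm_full.n:
                    continue
                rep = bootstrap_stability(
                    tm_full, meas, k,
                    replicates=cfg.stability_reps, seed=seeds["stability"],
                )
                sub = rep.per_cluster.copy()
                sub.insert(0, "k", k)
                sub.insert(0, "measure", meas)
                stab_frames.append(sub)
        if stab_frames:
            p = out / "stability.csv"
            pd.concat(stab_frames, ignore_index=True).to_csv(p, index=False)
            outputs.append(p)

        _stage("manifest")
        import sklearn

        manifest = {
            "config": asdict(cfg),
            "sub_seeds": seeds,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "sklearn": sklearn.__version__,
            },
            "outputs": {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in outputs
            },
        }
        manifest["outputs_hash"] = hashlib.sha256(
            json.dumps(manifest["outputs"], sort_keys=True).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline failed at stage {stage['name']!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
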