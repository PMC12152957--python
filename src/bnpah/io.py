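"""Tabular readers/writers and the end-to-end pipeline driver.

Interchange conventions: TSV for enumeration artifacts (scaffolds,
isomers), CSV for feature and property tables, JSON for configurations
and regression reports, concatenated XYZ for geometries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from bnpah import analysis, synthetic
from bnpah.bn_isomers import enumerate_bn_isomers
from bnpah.features import feature_table
from bnpah.molgraph import automorphism_group, build_molecular_graph, to_smiles
from bnpah.scaffolds import DualistTree, enumerate_scaffolds

logger = logging.getLogger(__name__)


def write_scaffolds(scaffolds, path) -> None:
    """One scaffold per line: canonical code, ring count, helicenic flag,
    semicolon-separated axial cells, semicolon-separated edges."""
    with open(path, "w") as fh:
        fh.write("canonical_code\tn_rings\thelicenic\tcells\tedges\n")
        for s in scaffolds:
            cells = ";".join(f"{q},{r}" for q, r in s.cells)
            edges = ";".join(f"{i},{j}" for i, j in s.edges)
            fh.write(f"{s.canonical_code}\t{s.n_rings}\t{int(s.helicenic)}\t{cells}\t{edges}\n")


def read_scaffolds(path) -> list[DualistTree]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        cells = tuple(
            tuple(int(x) for x in cell.split(",")) for cell in row["cells"].split(";")
        )
        edges = (
            tuple(tuple(int(x) for x in e.split(",")) for e in row["edges"].split(";"))
            if isinstance(row["edges"], str) and row["edges"]
            else ()
        )
        out.append(
            DualistTree(
                cells=cells,
                edges=edges,
                helicenic=bool(row["helicenic"]),
                canonical_code=row["canonical_code"],
            )
        )
    return out


def write_isomers(path, max_rings: int = 6, smiles: bool = False) -> pd.DataFrame:
    """Enumerate and write the isomer table; returns the DataFrame."""
    rows = []
    for tree in enumerate_scaffolds(max_rings):
        graph = build_molecular_graph(tree)
        group = automorphism_group(graph)
        for iso in enumerate_bn_isomers(graph, group):
            row = {
                "scaffold_code": iso.scaffold_code,
                "b_index": iso.b_index,
                "n_index": iso.n_index,
                "canonical_key": iso.canonical_key,
            }
            if smiles:
                from bnpah.bn_isomers import substituted_graph

                row["smiles"] = to_smiles(substituted_graph(graph, iso))
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run."""

    max_rings: int = 6
    out_dir: Path = Path("bnpah_out")
    seed: int = 0
    target: str = "gap"
    synthetic_config: synthetic.SyntheticModelConfig | None = None
    properties_path: Path | None = None  # load instead of synthesizing
    use_synthetic: bool = True
    restrict_to_n_rings: int | None = None

    def validate(self) -> None:
        if self.max_rings < 2:
            raise ValueError("max_rings must be at least 2")
        if not self.use_synthetic and self.properties_path is None:
            raise ValueError("synthesis disabled but no properties path given")


def run_pipeline(config: PipelineConfig) -> dict:
    """enumerate -> featurize -> properties -> e_rel -> trends -> model.

    Writes every stage artifact under ``config.out_dir`` and returns a
    summary dict with stage record counts and the regression report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scaffolds = enumerate_scaffolds(config.max_rings)
    write_scaffolds(scaffolds, out / "scaffolds.tsv")
    logger.info("enumerated %d scaffolds (<= %d rings)", len(scaffolds), config.max_rings)

    feats = feature_table(config.max_rings)
    feats.to_csv(out / "features.csv", index=False)
    logger.info("featurized %d isomers", len(feats))

    if config.use_synthetic:
        syn_cfg = config.synthetic_config or synthetic.SyntheticModelConfig(
            seed=config.seed
        )
        props = synthetic.generate_properties(feats, syn_cfg)
    else:
        props = synthetic.load_properties(config.properties_path)
    props = props.merge(feats, on="molecule_id")
    props = analysis.compute_e_rel(props)
    synthetic.save_properties(props[synthetic.PROPERTY_COLUMNS], out / "properties.csv")

    trends = {}
    for feature in ("n_rings", "n_LL", "n_SP", "n_DR"):
        restrict = None if feature == "n_rings" else (
            config.restrict_to_n_rings or config.max_rings
        )
        summary = analysis.trend_summary(
            props, feature, config.target, restrict_to_n_rings=restrict
        )
        trends[feature] = summary.table.to_dict(orient="records")

    report = analysis.ablation_study(props, config.target, seed=config.seed)
    result = {
        "n_scaffolds": len(scaffolds),
        "n_isomers": len(feats),
        "target": config.target,
        "trends": trends,
        "report": report.to_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(result, fh, indent=2)
    logger.info(
        "model on %s: test MAE %.4f, R2 %.4f",
        config.target,
        report.test_mae,
        report.test_r2,
    )
    return result
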