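"""End-to-end orchestration: enumerate stoichiometries, build, score,
dock, filter, analyze, classify.

The pipeline reproduces, on any pair of coiled-coil-forming sequences
plus an optional globular partner, the workflow used to weigh candidate
oligomeric states of a two-protein membrane-proximal subcomplex:

1. enumerate 1:1, 2:1, 1:2 and 2:2 bundles and build them on ideal
   Crick geometry;
2. derive (or load) a residue-pair contact potential and score each
   bundle;
3. rigid-body dock the partner onto each bundle (twice onto the 2:2
   bundle), filter poses by the declared membrane/interaction
   restraints;
4. compute the interface/surface descriptor tables, hotspot lists and a
   stability verdict per stoichiometry;
5. rank stoichiometries by (restraint-passing poses, stability verdict,
   pair-potential score) -- a declared synthesis of the qualitative
   selection narrative, labelled static-analysis only.

All outputs are plain TSV/JSON/PDB with fixed float formats; a run is a
pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .coiledcoil import (
    BundleSpec,
    build_bundle,
    enumerate_stoichiometries,
)
from .docking import (
    CoplanarityRestraint,
    DistanceRestraint,
    RestraintSet,
    apply_restraints,
    generate_poses,
    transform_ligand,
)
from .interface import classify_stability, interface_report, load_reference_row
from .mapping import alanine_scan
from .potential import (
    CB_CONTACTS,
    PairPotentialMatrix,
    derive_matrix,
    score_complex,
)
from .structure import Structure, read_fasta, read_pdb, write_pdb
from importlib import resources

logger = logging.getLogger("bundledock.pipeline")

STOICHIOMETRY_LABELS = ("1:1", "2:1", "1:2", "2:2")


class ConfigError(ValueError):
    pass


@dataclass
class ProteinSpec:
    name: str
    sequence: str
    start_seq_id: int = 1


@dataclass
class DockingConfig:
    enabled: bool = True
    partner: str = "synthetic"   # "synthetic" or a PDB path
    angular_step: float = 45.0
    spacing: float = 1.5
    keep_top: int = 50
    translations_per_rotation: int = 3
    double_dock_tetramer: bool = True


@dataclass
class RestraintConfig:
    coplanarity_slab: float | None = None
    distance: list[dict] = field(default_factory=list)

    def build(self) -> RestraintSet:
        rs = RestraintSet()
        if self.coplanarity_slab:
            rs.coplanarity = CoplanarityRestraint(slab_thickness=float(self.coplanarity_slab))
        for d in self.distance:
            rs.distance_restraints.append(
                DistanceRestraint(
                    [(str(c), int(s)) for c, s in d["receptor"]],
                    [(str(c), int(s)) for c, s in d["ligand"]],
                    float(d.get("max_distance", 6.0)),
                )
            )
        return rs


@dataclass
class PipelineConfig:
    protein_a: ProteinSpec
    protein_b: ProteinSpec
    stoichiometries: list[str] = field(default_factory=lambda: list(STOICHIOMETRY_LABELS))
    matrix_mode: str = "synthetic-bundles"  # or "load"
    matrix_path: str | None = None
    docking: DockingConfig = field(default_factory=DockingConfig)
    restraints: RestraintConfig = field(default_factory=RestraintConfig)
    out_dir: str = "pipeline_out"
    seed: int = 0

    _KNOWN = {
        "protein_a", "protein_b", "stoichiometries", "matrix_mode", "matrix_path",
        "docking", "restraints", "out_dir", "seed",
    }

    def __post_init__(self) -> None:
        for s in self.stoichiometries:
            if s not in STOICHIOMETRY_LABELS:
                raise ConfigError(f"unknown stoichiometry {s!r}")
        if self.matrix_mode not in ("synthetic-bundles", "load"):
            raise ConfigError(f"unknown matrix mode {self.matrix_mode!r}")
        if self.matrix_mode == "load" and not self.matrix_path:
            raise ConfigError("matrix_mode 'load' requires matrix_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        def protein(key, default_name, default_seq, default_start):
            d = raw.get(key) or {}
            return ProteinSpec(d.get("name", default_name),
                               d.get("sequence", default_seq),
                               int(d.get("start_seq_id", default_start)))
        seq_a, seq_b, start_a, start_b = _fixture_sequences()
        cfg = cls(
            protein_a=protein("protein_a", "FtsB-like", seq_a, start_a),
            protein_b=protein("protein_b", "FtsL-like", seq_b, start_b),
            stoichiometries=list(raw.get("stoichiometries", STOICHIOMETRY_LABELS)),
            matrix_mode=raw.get("matrix_mode", "synthetic-bundles"),
            matrix_path=raw.get("matrix_path"),
            docking=DockingConfig(**(raw.get("docking") or {})),
            restraints=RestraintConfig(**(raw.get("restraints") or {})),
            out_dir=raw.get("out_dir", "pipeline_out"),
            seed=int(raw.get("seed", 0)),
        )
        return cfg

    def digest(self) -> str:
        blob = json.dumps({
            "a": [self.protein_a.name, self.protein_a.sequence, self.protein_a.start_seq_id],
            "b": [self.protein_b.name, self.protein_b.sequence, self.protein_b.start_seq_id],
            "stoich": self.stoichiometries,
            "matrix": [self.matrix_mode, self.matrix_path],
            "docking": self.docking.__dict__,
            "restraints": [self.restraints.coplanarity_slab, self.restraints.distance],
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _fixture_sequences() -> tuple[str, str, int, int]:
    """Shipped synthetic stand-ins for the two periplasmic segments."""
    path = resources.files("bundledock").joinpath("data/sequences_synthetic.fasta")
    seqs: dict[str, str] = {}
    name = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line
    return seqs["FtsB_like_25-88"], seqs["FtsL_like_61-109"], 25, 61


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stoichiometry_specs(config: PipelineConfig) -> dict[str, BundleSpec]:
    specs = enumerate_stoichiometries(
        config.protein_a.sequence,
        config.protein_b.sequence,
        name_a=config.protein_a.name,
        name_b=config.protein_b.name,
        start_a=config.protein_a.start_seq_id,
        start_b=config.protein_b.start_seq_id,
    )
    return dict(zip(STOICHIOMETRY_LABELS, specs))


def training_matrix(config: PipelineConfig) -> PairPotentialMatrix:
    if config.matrix_mode == "load":
        return PairPotentialMatrix.from_tsv(config.matrix_path)
    train = []
    rng_seeds = range(config.seed + 1, config.seed + 9)
    for k, s in enumerate(rng_seeds):
        n = (2, 3, 4)[k % 3]
        st = synthetic.make_bundle(n, 28, "L", seed=s % (2**31))
        a_side = [cid for i, cid in enumerate(st.chains) if i % 2 == 0]
        b_side = [cid for i, cid in enumerate(st.chains) if i % 2 == 1]
        train.append((st, (a_side, b_side)))
    return derive_matrix(train, CB_CONTACTS)


def bundle_partition(st: Structure, spec: BundleSpec, name_a: str):
    a_side = [c.chain_id for c in spec.chains if c.identity == name_a]
    b_side = [c.chain_id for c in spec.chains if c.identity != name_a]
    return (a_side, b_side)


def load_partner(config: PipelineConfig) -> Structure:
    if config.docking.partner == "synthetic":
        partner = synthetic.make_groove_receptor(12.0, 8.0)
        # relabel to avoid collisions with bundle chain ids
        residues = partner.chains.pop("R")
        for r in residues:
            r.chain_id = "Q"
        partner.chains["Q"] = residues
        return partner
    return read_pdb(config.docking.partner)


def _relabel(structure: Structure, mapping: dict[str, str]) -> Structure:
    out = structure.copy()
    new = {}
    for cid, residues in out.chains.items():
        nid = mapping.get(cid, cid)
        for r in residues:
            r.chain_id = nid
        new[nid] = residues
    out.chains = new
    return out


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

TABLE1_COLUMNS = [
    "Complex", "Interface ASA (A2)", "Interface ASA %", "% Polar",
    "% Non polar", "% Charged", "H-bonds/100 A2", "Salt bridges/100 A2",
]
TABLE2_COLUMNS = ["Complex", "% Polar", "% Non polar", "% Charged"]


def render_tables(reports: dict[str, "object"], out_dir: Path, header: str) -> None:
    """Write the interface-parameter and surface-composition tables.

    One row per analysed complex plus the shipped mean-stable-complex
    reference row.
    """
    if not reports:
        raise ValueError("no reports to render")
    ref = load_reference_row()
    lines1 = [header, "\t".join(TABLE1_COLUMNS)]
    lines2 = [header, "\t".join(TABLE2_COLUMNS)]
    for label, rep in reports.items():
        lines1.append("\t".join([
            label,
            f"{rep.interface_asa:.2f}",
            f"{rep.interface_asa_percent:.2f}",
            f"{rep.interface_polar_pct:.2f}",
            f"{rep.interface_nonpolar_pct:.2f}",
            f"{rep.interface_charged_pct:.2f}",
            f"{rep.hbonds_per_100A2:.2f}",
            f"{rep.saltbridges_per_100A2:.2f}",
        ]))
        lines2.append("\t".join([
            label,
            f"{rep.surface_polar_pct:.2f}",
            f"{rep.surface_nonpolar_pct:.2f}",
            f"{rep.surface_charged_pct:.2f}",
        ]))
    sb = ref["saltbridges_per_100A2"]
    lines1.append("\t".join([
        ref["label"], "", f'{ref["interface_asa_percent"]}',
        f'{ref["interface_polar_pct"]}', f'{ref["interface_nonpolar_pct"]}',
        f'{ref["interface_charged_pct"]}', f'{ref["hbonds_per_100A2"]}',
        f"{sb[0]} - {sb[1]}",
    ]))
    lines2.append("\t".join([
        ref["label"], f'{ref["surface_polar_pct"]}',
        f'{ref["surface_nonpolar_pct"]}', f'{ref["surface_charged_pct"]}',
    ]))
    (out_dir / "table1_interface_parameters.tsv").write_text("\n".join(lines1) + "\n")
    (out_dir / "table2_surface_composition.tsv").write_text("\n".join(lines2) + "\n")


def _write_poses_tsv(poses, path: Path, header: str) -> None:
    from scipy.spatial.transform import Rotation

    lines = [header,
             "rank\tqw\tqx\tqy\tqz\ttx\tty\ttz\tcomplementarity\trotation_index\trestraints"]
    for k, p in enumerate(poses):
        q = Rotation.from_matrix(p.rotation).as_quat()  # x,y,z,w
        flags = ";".join(f"{k2}={'P' if v else 'F'}" for k2, v in sorted(p.restraint_flags.items())) or "-"
        lines.append(
            f"{k + 1}\t{q[3]:.6f}\t{q[0]:.6f}\t{q[1]:.6f}\t{q[2]:.6f}"
            f"\t{p.translation[0]:.3f}\t{p.translation[1]:.3f}\t{p.translation[2]:.3f}"
            f"\t{p.complementarity_score:.6f}\t{p.rotation_index}\t{flags}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_hotspots_tsv(hotspots, path: Path, header: str) -> None:
    lines = [header, "chain\tseq_id\tresidue\tddG_proxy\tinteractions\tpartner_chain\tscannable"]
    for h in hotspots:
        lines.append(
            f"{h.residue[0]}\t{h.residue[1]}\t{h.residue[2]}\t{h.ddg_proxy:.4f}"
            f"\t{','.join(h.interactions_lost) or '-'}\t{h.partner_chain or '-'}"
            f"\t{'yes' if h.scannable else 'no'}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

VERDICT_RANK = {"consistent": 0, "borderline": 1, "inconsistent": 2}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every requested stoichiometry.

    Returns a result dict with per-stoichiometry records and writes the
    report bundle under ``config.out_dir``.  Stage failures are logged
    and recorded; independent later stages still run.
    """
    t_start = time.time()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    header = f"# bundledock pipeline config={config.digest()} seed={config.seed}"
    specs = stoichiometry_specs(config)
    result: dict = {"stoichiometries": {}, "failures": [], "config_digest": config.digest()}

    try:
        matrix = training_matrix(config)
        matrix.to_tsv(out_root / "pair_potential.tsv")
    except Exception as exc:  # pragma: no cover - defensive
        logger.exception("matrix stage failed")
        result["failures"].append(("matrix", str(exc)))
        matrix = None

    partner = None
    if config.docking.enabled:
        try:
            partner = load_partner(config)
        except Exception as exc:
            logger.exception("partner loading failed")
            result["failures"].append(("partner", str(exc)))

    reports = {}
    for label in config.stoichiometries:
        spec = specs[label]
        rec: dict = {"label": label}
        sdir = out_root / label.replace(":", "-")
        sdir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            bundle = build_bundle(spec)
            write_pdb(bundle, sdir / "bundle.pdb")
            partition = bundle_partition(bundle, spec, config.protein_a.name)
            rec["n_chains"] = len(spec.chains)
        except Exception as exc:
            logger.exception("build stage failed for %s", label)
            result["failures"].append((f"build:{label}", str(exc)))
            result["stoichiometries"][label] = rec
            continue

        if matrix is not None:
            try:
                rec["pair_potential_score"] = round(
                    score_complex(bundle, partition, matrix), 4)
            except Exception as exc:
                result["failures"].append((f"score:{label}", str(exc)))

        complex_structure = bundle
        complex_partition = partition
        if config.docking.enabled and partner is not None:
            try:
                poses = generate_poses(
                    bundle, partner,
                    angular_step=config.docking.angular_step,
                    spacing=config.docking.spacing,
                    keep_top=config.docking.keep_top,
                    translations_per_rotation=config.docking.translations_per_rotation,
                )
                restraints = config.restraints.build()
                kept = apply_restraints(poses, bundle, partner, restraints) if (
                    restraints.distance_restraints or restraints.coplanarity
                ) else list(poses)
                _write_poses_tsv(poses, sdir / "poses.tsv", header)
                _write_poses_tsv(kept, sdir / "filtered_poses.tsv", header)
                rec["n_poses"] = len(poses)
                rec["n_restraint_pass"] = len(kept)
                if kept:
                    placed = transform_ligand(partner, kept[0])
                    n_partners = 1
                    if label == "2:2" and config.docking.double_dock_tetramer:
                        # mirror the first accepted pose through the bundle
                        # axis (C2 shortcut) for the second partner copy
                        mirror = np.diag([-1.0, -1.0, 1.0])
                        second = placed.transformed(mirror, np.zeros(3))
                        second = _relabel(second, {cid: cid.lower() for cid in second.chains})
                        complex_structure = bundle.merged(placed).merged(second)
                        n_partners = 2
                    else:
                        complex_structure = bundle.merged(placed)
                    rec["n_partners_docked"] = n_partners
                    partner_ids = [c for c in complex_structure.chains
                                   if c not in bundle.chains]
                    complex_partition = (list(bundle.chains), partner_ids)
                    write_pdb(complex_structure, sdir / "complex.pdb")
            except Exception as exc:
                logger.exception("docking stage failed for %s", label)
                result["failures"].append((f"dock:{label}", str(exc)))

        try:
            # 240 sphere points: ~0.5% SASA accuracy, adequate for the
            # percentage/density descriptors at report precision
            rep = interface_report(complex_structure, complex_partition, n_points=240)
            reports[label] = rep
            (sdir / "interface_report.json").write_text(
                json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")
            verdict = classify_stability(rep)
            (sdir / "stability.json").write_text(
                json.dumps(verdict, indent=2, sort_keys=True) + "\n")
            rec["stability"] = verdict["verdict"]
            rec["interface_asa"] = rep.interface_asa
        except Exception as exc:
            logger.exception("interface stage failed for %s", label)
            result["failures"].append((f"interface:{label}", str(exc)))

        if matrix is not None:
            try:
                # rebind the derived scores to the heavy-atom contact rule:
                # CB-CB contacts are blind to side-chain truncation
                from .potential import ContactDefinition

                scan_matrix = PairPotentialMatrix(
                    matrix.scores, matrix.pseudocount,
                    ContactDefinition("heavy", 4.5),
                    matrix.training_provenance + " (heavy-atom rebind for scanning)",
                )
                keys = reports[label].interface_residue_keys if label in reports else None
                hotspots = alanine_scan(complex_structure, complex_partition,
                                        scan_matrix, interface_residue_keys=keys)
                _write_hotspots_tsv(hotspots, sdir / "hotspots.tsv", header)
                rec["n_hotspots"] = sum(1 for h in hotspots if h.ddg_proxy > 0)
                # also scan the coiled-coil interface of the bundle itself
                bundle_spots = alanine_scan(bundle, partition, scan_matrix)
                _write_hotspots_tsv(bundle_spots, sdir / "hotspots_bundle.tsv", header)
                rec["n_bundle_hotspots"] = sum(1 for h in bundle_spots if h.ddg_proxy > 0)
            except Exception as exc:
                logger.exception("hotspot stage failed for %s", label)
                result["failures"].append((f"hotspots:{label}", str(exc)))

        rec["elapsed_s"] = round(time.time() - t0, 2)
        result["stoichiometries"][label] = rec

    if reports:
        render_tables(reports, out_root, header)

    # summary ranking: restraint-passing poses desc, stability verdict,
    # pair-potential score desc (declared heuristic, static analysis only)
    rows = []
    for label, rec in result["stoichiometries"].items():
        rows.append((
            -(rec.get("n_restraint_pass", 0)),
            VERDICT_RANK.get(rec.get("stability"), 3),
            -(rec.get("pair_potential_score", float("-inf")) or 0.0),
            label,
        ))
    rows.sort()
    lines = [header,
             "rank\tstoichiometry\tn_restraint_pass\tstability\tpair_potential_score\tnote"]
    for rank, (_, _, _, label) in enumerate(rows, start=1):
        rec = result["stoichiometries"][label]
        lines.append(
            f"{rank}\t{label}\t{rec.get('n_restraint_pass', 0)}"
            f"\t{rec.get('stability', 'n/a')}\t{rec.get('pair_potential_score', 'n/a')}"
            f"\tstatic-analysis only"
        )
    (out_root / "summary.tsv").write_text("\n".join(lines) + "\n")
    result["elapsed_s"] = round(time.time() - t_start, 2)
    result["ok"] = not result["failures"]
    return result
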