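"""YAML job specification and scan orchestration.

``run_scan`` drives the full protocol per mutation: conformation spaces →
energy matrices → ε-bounded partition functions → K* → ΔK* against the
same-run wildtype → triage, with the signature-probability stage appended
when a cancer type is configured.  Outputs are deterministic: fixed
ordering, fixed float formatting, and a provenance header (config hash and
seed) on every table, so a rerun at the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .confspace import (
    AA3_TO_1,
    ALL_AA1,
    MutationSpec,
    RotamerLibrary,
    build_conf_spaces,
    enumerate_mutations,
)
from .energetics import compute_energy_matrix
from .kstar import (
    DEFAULT_TEMPERATURE,
    DeltaKStar,
    delta_kstar,
    kstar_score,
    partition_function_bounded,
)
from .mutprob import (
    GeneSequence,
    MutationProbability,
    SignatureCatalog,
    codon_paths,
    load_weights_tsv,
    mutation_probability,
    rank_probabilities,
    probability_table,
)
from .structures import ResidueSite, Structure, find_interface_residues, read_structure, trim_to_shell
from .triage import (
    DisruptionCall,
    TriageConfig,
    calls_table,
    classify_disruption,
    heatmap_matrix,
    hotspot_rank,
    prioritize,
)

logger = logging.getLogger("bindscan")

_JOB_KEYS = {
    "structure_path", "partner_a_chains", "partner_b_chains", "mutable",
    "allowed_mutations", "pair_mode", "epsilon", "temperature", "cutoff",
    "his_rule", "exclude_triples", "interface_cutoff", "shell_radius",
    "cancer_type", "gene_path", "gene_chain", "gene_offset",
    "signatures_path", "weights_path", "seed", "top_k", "subsample_rotamers",
    "synthetic_offsets",
}


@dataclass
class JobSpec:
    structure_path: str
    partner_a_chains: List[str]
    partner_b_chains: List[str]
    mutable: object = "auto-interface"  # list of "CHAIN:NUM[:ICODE]" or "auto-interface"
    allowed_mutations: object = "ALL"  # "ALL", list of aa codes, or per-site dict
    pair_mode: bool = False
    epsilon: float = 0.03
    temperature: float = DEFAULT_TEMPERATURE
    triage: TriageConfig = field(default_factory=TriageConfig)
    interface_cutoff: float = 5.0
    shell_radius: float = 12.0
    cancer_type: Optional[str] = None
    gene_path: Optional[str] = None
    gene_chain: Optional[str] = None
    gene_offset: int = 0  # protein_position = residue_number - gene_offset
    signatures_path: Optional[str] = None
    weights_path: Optional[str] = None
    seed: int = 0
    top_k: int = 3
    subsample_rotamers: bool = False
    # synthetic-validation hook: {"SITE_LABEL:TARGET_AA": kcal/mol added to
    # the mutant's complex template energy}
    synthetic_offsets: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be positive")
        if self.interface_cutoff <= 0:
            raise ValueError("interface_cutoff must be positive")
        if self.cancer_type is not None and self.gene_path is None:
            raise ValueError("cancer_type set but no gene_path given")

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_job(yaml_text: str) -> JobSpec:
    """Parse and validate a YAML job; unknown keys are rejected."""
    raw = yaml.safe_load(yaml_text)
    if not isinstance(raw, dict):
        raise ValueError("job YAML must be a mapping")
    unknown = set(raw) - _JOB_KEYS
    if unknown:
        raise ValueError(f"unknown job key(s): {sorted(unknown)}")
    if "structure_path" not in raw:
        raise ValueError("job must name a structure_path")
    for k in ("partner_a_chains", "partner_b_chains"):
        if k not in raw:
            raise ValueError(f"job must name {k}")
    triage_kwargs = {}
    for src, dst in (("cutoff", "cutoff"), ("his_rule", "his_rule"),
                     ("exclude_triples", "exclude_triples")):
        if src in raw:
            triage_kwargs[dst] = raw.pop(src)
    raw["triage"] = TriageConfig(**triage_kwargs)
    raw["partner_a_chains"] = [str(c) for c in raw["partner_a_chains"]]
    raw["partner_b_chains"] = [str(c) for c in raw["partner_b_chains"]]
    job = JobSpec(**raw)
    if job.pair_mode:
        if not isinstance(job.mutable, list) or len(job.mutable) != 2:
            raise ValueError("pair_mode requires exactly 2 mutable sites")
    return job


def _parse_site(label: str, structure: Structure) -> ResidueSite:
    parts = str(label).split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"bad site label {label!r} (expected CHAIN:RESNUM[:ICODE])")
    chain, num = parts[0], int(parts[1])
    icode = parts[2] if len(parts) == 3 else ""
    for s in structure.sites:
        if (s.chain_id, s.residue_number, s.insertion_code) == (chain, num, icode):
            return s
    raise KeyError(f"site {label!r} not found in structure")


def _allowed_for(job: JobSpec, site: ResidueSite) -> List[str]:
    allowed = job.allowed_mutations
    if isinstance(allowed, dict):
        allowed = allowed.get(site.label, allowed.get("default", "ALL"))
    if allowed == "ALL":
        return list(ALL_AA1)
    return [str(a) for a in allowed]


@dataclass
class ScanResult:
    calls: List[DisruptionCall]
    scores: "object"  # pandas DataFrame of raw per-variant scores
    hotspots: "object"
    heatmap: "object"
    priorities: "object"
    probabilities: Optional[List[MutationProbability]]
    provenance: Dict[str, str]


def _score_mutation(
    structure: Structure,
    flexible_sites: List[ResidueSite],
    spec: Optional[MutationSpec],
    library: RotamerLibrary,
    job: JobSpec,
    complex_offset: float = 0.0,
):
    """K* for one sequence (wildtype when ``spec`` is None/reference)."""
    cs_c, cs_a, cs_b = build_conf_spaces(structure, flexible_sites, spec, library)
    m_c = compute_energy_matrix(cs_c)
    if complex_offset:
        m_c.template_energy += complex_offset
    m_a = compute_energy_matrix(cs_a)
    m_b = compute_energy_matrix(cs_b)
    if spec is not None and not spec.is_reference:
        # restrict the {wildtype, target} position to the target sequence
        target_type = spec.residue_type
        for m in (m_c, m_a, m_b):
            for pi, keys in enumerate(m.position_keys):
                types = {k[1] for k in keys}
                if len(types) > 1:
                    m.position_keys[pi] = [k for k in keys if k[1] == target_type]
    pfs = [
        partition_function_bounded(m, job.temperature, job.epsilon)
        for m in (m_c, m_a, m_b)
    ]
    return kstar_score(*pfs)


def run_scan(job: JobSpec, out_dir: Optional[str] = None) -> ScanResult:
    """Execute the full interface-mutation scan defined by ``job``."""
    import pandas as pd

    with open(job.structure_path) as fh:
        pdb_text = fh.read()
    structure = read_structure(pdb_text, job.partner_a_chains, job.partner_b_chains)
    interface = find_interface_residues(structure, job.interface_cutoff)
    if interface:
        structure = trim_to_shell(structure, interface, job.shell_radius)

    if job.mutable == "auto-interface":
        mutable_sites = sorted(
            (s for s in interface if s.is_protein()), key=ResidueSite.sort_key
        )
        if not mutable_sites:
            raise ValueError("auto-interface found no protein interface residues")
    else:
        mutable_sites = [_parse_site(lbl, structure) for lbl in job.mutable]
    if job.pair_mode and len(mutable_sites) != 2:
        raise ValueError("pair_mode requires exactly 2 mutable sites")

    library = RotamerLibrary.default(subsample=job.subsample_rotamers)

    gene: Optional[GeneSequence] = None
    weights = None
    catalog: Optional[SignatureCatalog] = None
    if job.gene_path:
        with open(job.gene_path) as fh:
            from Bio import SeqIO

            record = next(SeqIO.parse(fh, "fasta"))
            desc = dict(
                kv.split("=") for kv in record.description.split() if "=" in kv
            )
            gene = GeneSequence(
                str(record.seq), desc.get("flank5", "A"), desc.get("flank3", "A")
            )
    if job.cancer_type:
        if not (job.signatures_path and job.weights_path):
            raise ValueError("cancer_type requires signatures_path and weights_path")
        with open(job.signatures_path) as fh:
            catalog = SignatureCatalog.from_tsv(fh.read())
        with open(job.weights_path) as fh:
            weights = load_weights_tsv(fh.read(), job.cancer_type)

    calls: List[DisruptionCall] = []
    score_rows: List[Dict] = []
    probs: List[MutationProbability] = []

    def flexible_for(site: ResidueSite) -> List[ResidueSite]:
        # pair mode: both sites flexible in every evaluation ("investigated
        # in pairs"); otherwise one flexible site per evaluation
        return list(mutable_sites) if job.pair_mode else [site]

    wt_scores: Dict[ResidueSite, object] = {}
    for site in mutable_sites:
        logger.info("wildtype reference at %s", site.label)
        wt_scores[site] = _score_mutation(
            structure, flexible_for(site), None, library, job
        )
        if wt_scores[site].status != "OK":
            raise RuntimeError(f"wildtype K* failed at {site.label}")

    for site in mutable_sites:
        wt_score = wt_scores[site]
        wt1 = AA3_TO_1[site.residue_type]
        specs = enumerate_mutations(site, _allowed_for(job, site))
        by_target: Dict[str, List[Tuple[MutationSpec, DeltaKStar]]] = {}
        for spec in specs:
            try:
                if spec.is_reference:
                    delta = delta_kstar(wt_score, wt_score, spec)
                else:
                    offset = job.synthetic_offsets.get(
                        f"{site.label}:{spec.target_aa}", 0.0
                    )
                    mut_score = _score_mutation(
                        structure, flexible_for(site), spec, library, job,
                        complex_offset=offset,
                    )
                    delta = delta_kstar(mut_score, wt_score, spec)
            except Exception as exc:  # per-mutation failures are not fatal
                logger.warning("mutation %s failed: %s", spec.label, exc)
                continue
            by_target.setdefault(spec.target_aa, []).append((spec, delta))
            score_rows.append(
                {
                    "site": site.label,
                    "position": site.residue_number,
                    "wildtype_aa": wt1,
                    "target_aa": spec.target_aa,
                    "variant": spec.protonation_variant or "",
                    "delta_kstar": delta.display,
                    "wildtype_log10_kstar": f"{wt_score.score:.4f}",
                }
            )

        prot_pos = site.residue_number - job.gene_offset
        for target, entries in sorted(by_target.items()):
            deltas = [d for _, d in entries]
            path_class = "single"
            if target != wt1 and gene is not None and (
                job.gene_chain is None or site.chain_id == job.gene_chain
            ):
                paths = codon_paths(gene.codon(prot_pos), target)
                path_class = min(
                    (p.path_class for p in paths),
                    key=lambda c: {"single": 1, "double": 2, "triple": 3}[c],
                )
                if weights is not None and catalog is not None:
                    probs.append(
                        mutation_probability(gene, prot_pos, target, weights, catalog)
                    )
            if target == wt1:
                continue  # reference row: not a call
            calls.append(
                classify_disruption(
                    deltas,
                    path_class=path_class,
                    cfg=job.triage,
                    position=site.residue_number,
                    wildtype_aa=wt1,
                    target_aa=target,
                    chain_id=site.chain_id,
                )
            )

    hotspots = hotspot_rank(calls, top_k=job.top_k)
    heatmap = heatmap_matrix(calls)
    ranked_probs = rank_probabilities(probs) if probs else None
    hotspot_probs = None
    if ranked_probs is not None:
        from dataclasses import replace as _dc_replace

        top = set(hotspots.top_positions)
        # prioritize matches on residue-number positions: shift copies
        hotspot_probs = [
            _dc_replace(p, protein_position=p.protein_position + job.gene_offset)
            for p in ranked_probs
            if p.protein_position + job.gene_offset in top
        ]
    priorities = prioritize(calls, hotspots, hotspot_probs)

    provenance = {
        "tool": f"bindscan {__version__}",
        "config_hash": job.config_hash(),
        "seed": str(job.seed),
        "epsilon": str(job.epsilon),
        "temperature": str(job.temperature),
        "cutoff": str(job.triage.cutoff),
    }
    result = ScanResult(
        calls=calls,
        scores=pd.DataFrame(score_rows),
        hotspots=hotspots,
        heatmap=heatmap,
        priorities=priorities,
        probabilities=ranked_probs,
        provenance=provenance,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _write_csv(df, path: str, provenance: Dict[str, str]) -> None:
    header = "".join(f"# {k}: {v}\n" for k, v in provenance.items())
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(df.to_csv(index=False))


def write_outputs(result: ScanResult, out_dir: str) -> List[str]:
    os.makedirs(out_dir, exist_ok=True)
    prov = result.provenance
    written = []
    for name, df in (
        ("scores.csv", result.scores),
        ("calls.csv", calls_table(result.calls)),
        ("hotspots.csv", result.hotspots.to_frame()),
        ("priorities.csv", result.priorities),
    ):
        path = os.path.join(out_dir, name)
        _write_csv(df, path, prov)
        written.append(path)
    path = os.path.join(out_dir, "heatmap.csv")
    header = "".join(f"# {k}: {v}\n" for k, v in prov.items())
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(result.heatmap.to_csv())
    written.append(path)
    if result.probabilities is not None:
        path = os.path.join(out_dir, "probabilities.csv")
        _write_csv(probability_table(result.probabilities), path, prov)
        written.append(path)
    return written
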