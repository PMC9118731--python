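"""End-to-end report pipeline with provenance.

Chains segmentation -> composition -> disorder -> thermodynamics ->
electrostatic patches -> hydrogen bonds -> oscillator simulation into one
deterministic TSV/JSON bundle.  Inputs default to the synthetic fixtures,
so a complete report needs no network access; every stage's parameters and
output hashes land in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anksim, assays, disorder, electropatch, hbonds
from . import repeats as rp
from . import synthetic, thermo
from .structures import extract_sequence

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "results/report"
    seed: int = 0
    n_repeats: int = 7
    start_number: int = 1872
    score_target: float = 0.37
    score_ref: float = 0.21
    n_residues: int = 230
    deltaG0: float = -8.0
    ndof: int = 3
    heat_power_nw: float = 20.0
    heat_mass_ng: float = 1.0
    heat_duration_s: float = 1.0
    sim_steps: int = 50_000
    sim_seeds: int = 5
    sim_temps: tuple[float, float] = (310.15, 312.15)
    ionic_strength: float = 0.15
    eps_solvent: float = 78.0
    temperature_k: float = 298.15
    patch_threshold: float = -5.0
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 120.0

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.sim_temps, list):
            cfg.sim_temps = tuple(cfg.sim_temps)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=True)
        written.append(p)

    def save_json(obj: dict, name: str) -> None:
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        written.append(p)

    # -- stage 1: repeat anatomy on the idealized domain -------------------
    spec = synthetic.RepeatGeometrySpec(
        n_repeats=config.n_repeats, start_number=config.start_number,
    )
    model = synthetic.make_repeat_structure(spec)
    seq = extract_sequence(model, spec.chain_id)
    ann = rp.segment_repeats(seq)
    ann = rp.assign_elements(ann, model, spec.chain_id)
    save_tsv(
        pd.DataFrame([
            {"repeat": r.index, "start": r.span[0], "end": r.span[1],
             "score": round(r.score, 3)}
            for r in ann.repeats
        ]).set_index("repeat"),
        "repeats.tsv",
    )

    labels = [lab for r in ann.repeats for lab in r.element_labels]
    domain_letters = "".join(
        seq.letters[i] for i, n in enumerate(seq.numbering)
        if any(r.span[0] <= n <= r.span[1] for r in ann.repeats)
    )
    domain_seq = type(seq)("domain", domain_letters)
    helix = rp.composition_profile(domain_seq, labels, "α-helix")
    hairpin = rp.composition_profile(domain_seq, labels, "β-hairpin")
    save_tsv(
        pd.DataFrame({
            "helix": pd.Series(helix.frequencies),
            "hairpin": pd.Series(hairpin.frequencies),
        }).fillna(0.0).round(4),
        "composition.tsv",
    )

    # -- stage 2: disorder -------------------------------------------------
    prof = disorder.disorder_profile(seq)
    save_tsv(
        pd.DataFrame({"residue": prof.numbering, "score": prof.scores.round(4)}
                     ).set_index("residue"),
        "disorder.tsv",
    )

    # -- stage 3: thermodynamics (printed score averages as inputs) --------
    params = thermo.ThermoParams(
        score_target=config.score_target, score_ref=config.score_ref,
        n_residues=config.n_residues, deltaG0=config.deltaG0,
        ndof=config.ndof,
    )
    budget = thermo.HeatBudget(
        power=config.heat_power_nw, mass=config.heat_mass_ng,
        duration=config.heat_duration_s,
    )
    save_json(thermo.sensor_report(params, budget), "thermo.json")

    # -- stage 4: electrostatic patches on a planted two-cluster fixture ---
    fixture, expected = synthetic.make_charge_fixture(
        [((0.0, 0.0, 0.0), 4, -1), ((80.0, 0.0, 0.0), 3, -1)],
        ionic_strength=config.ionic_strength,
    )
    cm = electropatch.assign_charges(fixture)
    pts, areas, owners = electropatch.sample_surface(fixture)
    pmap = electropatch.screened_potential(
        cm, pts, areas, owners, config.ionic_strength,
        config.eps_solvent, config.temperature_k,
    )
    patches = electropatch.detect_patches(pmap, config.patch_threshold, "neg")
    save_tsv(
        pd.DataFrame([
            {"patch": i + 1, "area_A2": round(p.area, 1),
             "mean_potential": round(p.mean_potential, 2),
             "residues": ",".join(p.member_residues)}
            for i, p in enumerate(patches)
        ]).set_index("patch"),
        "patches.tsv",
    )

    # -- stage 5: interface hydrogen bonds on the synthetic ternary complex
    ternary = synthetic.notch_ternary_complex()
    inv = hbonds.interface_inventory(
        ternary, {"ANK": ["A"], "MAML1": ["B"], "RBPJ": ["C"]},
        config.hbond_dmax, config.hbond_angle_min,
    )
    save_json(
        {
            "criteria": {"d_max_A": config.hbond_dmax,
                         "angle_min_deg": config.hbond_angle_min},
            "counts": {f"{a}|{b}": n for (a, b), n in inv.counts.items()},
            "ank_maml1_via_E2008_D1972": inv.residue_subcount(
                "ANK", "MAML1", {"A:GLU2008", "A:ASP1972"}),
        },
        "hbonds.json",
    )

    # -- stage 6: oscillator simulation ------------------------------------
    chain = anksim.notch_preset()
    seeds = [config.seed + i for i in range(config.sim_seeds)]
    rows = []
    for temp in config.sim_temps:
        rmsf = anksim.ensemble_rmsf(chain, temp, config.sim_steps, seeds=seeds)
        rows.append({"temperature_K": temp,
                     **{f"repeat_{i+1}": round(v, 5) for i, v in enumerate(rmsf)}})
    mut = anksim.mutate_charge(chain, 4, chain.charges[3] * 0.3)
    rmsf_mut = anksim.ensemble_rmsf(mut, config.sim_temps[-1],
                                    config.sim_steps, seeds=seeds)
    rows.append({"temperature_K": config.sim_temps[-1],
                 **{f"repeat_{i+1}": round(v, 5) for i, v in enumerate(rmsf_mut)},
                 "variant": "charge_mutant_repeat4"})
    save_tsv(pd.DataFrame(rows).set_index("temperature_K"), "rmsf.tsv")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "tool": "ankylotherm",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
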