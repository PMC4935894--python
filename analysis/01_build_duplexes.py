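#!/usr/bin/env python
"""Build the response-element duplexes used throughout the analysis.

Generates ideal B-form duplexes for the unmethylated GRE and its side-
(smGRE) and middle-methylated (mmGRE) variants — the methylated builds
carry the documented methylation-coupled slide at A-mC steps — plus the
ERE and E-box elements.  Structures go to scratch/structures/ (PDB);
a per-duplex summary table goes to results/duplexes.tsv.
"""

from pathlib import Path

from basestack import dna_geometry as dg
from basestack import structure_io as sio
from basestack import synthetic_data as syn

SCRATCH = Path("scratch/structures")
RESULTS = Path("results")


def builds():
    yield "GRE", syn.GRE, (), None
    sm_overrides = syn.methylation_slide_steps(syn.SMGRE, syn.SMGRE_CRICK_MC)
    yield "smGRE", syn.SMGRE, syn.SMGRE_CRICK_MC, sm_overrides
    mm_overrides = syn.methylation_slide_steps(syn.MMGRE)
    yield "mmGRE", syn.MMGRE, (), mm_overrides or None
    yield "ERE", syn.ERE, (), None
    yield "Ebox", syn.EBOX, (), None


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, seq, crick_mc, overrides in builds():
        s = syn.build_bdna(seq, step_params=overrides,
                           crick_methylations=crick_mc, structure_id=name)
        pairs = dg.detect_base_pairs(s, "A", "B")
        steps = dg.build_steps(pairs)
        path = SCRATCH / f"{name.lower()}.pdb"
        sio.write_structure(s, path)
        n_mc = sum(r.base_code == "mC" for r in s.residues())
        rows.append({
            "element": name, "sequence": seq, "n_bp": len(pairs),
            "n_steps": len(steps), "n_mC": n_mc,
            "slid_steps": ",".join(str(k + 1) for k in sorted(overrides))
            if overrides else "-",
            "pdb": str(path),
        })
        print(f"{name}: {len(pairs)} bp, {len(steps)} steps, "
              f"{n_mc} mC -> {path}")
    sio.write_report(rows, RESULTS / "duplexes.tsv")
    print(f"summary -> {RESULTS / 'duplexes.tsv'}")


if __name__ == "__main__":
    main()
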