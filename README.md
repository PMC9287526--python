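# dopasight

Predict which tyrosines of an adhesive (fusion) protein are accessible to
tyrosinase, convert them to L-DOPA in the structure, and account for the
consequences: modification-dependent molecular weight and pH-dependent
catechol/quinone adhesion state.

The pipeline is: Shrake–Rupley solvent-accessible surface area → relative
accessibility against a theoretical-maximum table → tyrosine classification
(whole-residue threshold, strictly above 55% by default, or exposure of the
CE1/CE2 ring carbons) → in-structure Tyr→DOPA conversion (residue renamed to
`DAH`, one ring oxygen added in-plane at 1.36 Å from CE1) → mass bookkeeping
and a rule-based pH adhesion assessment.

## Modules

| module | what it does |
|---|---|
| `dopasight.io_bio` | FASTA records, precursor signal/mature splitting, PDB v3.3 read/write |
| `dopasight.sasa` | Shrake–Rupley SASA (deterministic spiral, grid neighbour search) + seeded Monte-Carlo oracle |
| `dopasight.predict` | tyrosine classification, DOPA conversion, end-to-end pipeline |
| `dopasight.mass` | average sequence mass; oxygen bookkeeping in two conventions (2 or 1 oxygens booked per DOPA) |
| `dopasight.ph` | step-function catechol/quinone state vs pH, qualitative adhesion |
| `dopasight.geometry` | phi/psi dihedrals with coarse Ramachandran regions, radius of gyration, Kabsch RMSD |
| `dopasight.fixtures` | deterministic synthetic structures (exposed/buried tyrosines, toy chimera) and the bundled MFP3/CsgA precursor sequences |
| `dopasight.cli` | `dopasight` command with subcommands |

## CLI

```sh
dopasight fixture --kind toy_chimera --out toy.pdb --param k=4 --param m=3
dopasight sasa toy.pdb --probe 1.4 --points 960 --per-residue sasa.tsv
dopasight predict toy.pdb --threshold 0.55 --mode whole_residue \
    --out-structure modified.pdb --report report.tsv
dopasight mass --uw 20.385 --n-dopa 7            # -> mw 20.609 kDa
dopasight mass --delta 224                        # -> 7 DOPA
dopasight ph --n-dopa 7 --ph 3,5,7.4,9
dopasight geom toy.pdb --ref modified.pdb
dopasight report toy.pdb --uw 20.385 --out-prefix run1
```

Settings may also come from a TOML config (`--config`) with sections
`[sasa]`, `[accessibility]`, `[mass]`, `[ph]`; CLI flags override the config,
which overrides the defaults.

## Conventions worth knowing

- Relative accessibility = residue SASA / theoretical maximum (Tien et al.
  2013 values, shipped in `dopasight/data/max_asa.tsv`, swappable).
- The default mass convention books **two** oxygens per DOPA (both ring
  hydroxyls counted as added mass, 224 Da for 7 DOPA); the chemically
  standard single-oxygen convention is available as `MassModel.chemical()`.
  Every output names the active convention.
- The pH model is an explicit step function (catechol ≤ 6.5 < quinone by
  default), not a fitted titration curve.
- Hydrogens are parsed but excluded from SASA by default; blocker
  pseudo-atoms in fixtures are HETATM records in a separate chain, so they
  shadow surface area without taking part in residue-level logic.
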