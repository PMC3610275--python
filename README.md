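# gpcrgeom

Structural analysis of the TM6/TM7 micro-switch region of class A GPCRs:
generic (T.NN) residue numbering anchored on the conserved TM6 CWxP and TM7
NPxxY motifs, chi1 rotamer classification (g+/g-/t), HELANAL-style unit
twist/bend helix profiling around proline kinks, sulfur/oxygen donor
hydrogen-bond geometry (D···A distance, Cβ–D···A angle), Asn/Gln amide-flip
assessment, and hydrogen-bond network scans — plus synthetic generators for
every fixture the analyses need (ideal/kinked helical peptides with exact
phi/psi/chi1, perturbed conformational ensembles, engineered donor–acceptor
fixtures, toy alignments).

## Layout

| module | contents |
| --- | --- |
| `gpcrgeom.structure_io` | PDB read/write (multi-model ensembles, alt-loc resolution, gzip), coordinate/topology model |
| `gpcrgeom.bw_numbering` | motif-anchored generic numbering, alignment column frequencies |
| `gpcrgeom.helix_geometry` | dihedrals, phi/psi, local helix axes, unit twist/bend profiles |
| `gpcrgeom.rotamers` | chi1, rotamer classification, population tables |
| `gpcrgeom.interaction_geometry` | donor–acceptor geometry, H-bond verdicts, amide flips, network scans, tabular reports |
| `gpcrgeom.profile_compare` | circular ensemble averaging, profile deltas, distortion flags, plots |
| `gpcrgeom.synthetic_structures` | peptide/ensemble/fixture/alignment generators |

## CLI

```sh
gpcrgeom build-peptide --sequence AAAAAAAAAACAAPAAAAAAAAAAA --chi1 10:-60 -o pep.pdb
gpcrgeom build-conformers -d conformers/          # AAAP + 9 chi1 conformers
gpcrgeom perturb --sequence ... --n-frames 100 --sigma 0.05 --seed 1 -o ens.pdb
gpcrgeom hbond-fixture --donor CYS --acceptor ASN --distance 3.8 --angle 84.5 -o fix.pdb
gpcrgeom toy-alignment --n-seqs 1000 --spec '{"6.47": {"C": 0.7}}' --seed 1 -o aln.fasta

gpcrgeom bw-map receptor.pdb                      # motif-anchored numbering
gpcrgeom profile pep.pdb --motif-res 11           # phi/psi/bend/twist TSV
gpcrgeom ensemble-profile ens.pdb --motif-res 11 --reference ref.pdb
gpcrgeom rotamer-report receptor.pdb --residues CYS,SER,THR
gpcrgeom measure-pair receptor.pdb --donor 6.47 --acceptor 7.45
gpcrgeom network receptor.pdb --positions 2.50,3.39,6.43,6.47,7.45,7.49 --waters
```

Explicit anchor configs (for positions such as 2.50/3.39 that have no
locally unique motif) are JSON: `{"6.50": "A:288", "2.50": "A:79"}`.

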