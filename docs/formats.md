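# File formats

All formats are plain text.  The XML dialects below are defined by the
fixture writers in `qsconsensus.fixtures` and consumed by
`qsconsensus.adapters`; real PISA/EPPIC exports may need a thin
element-renaming layer.

## Annotation table (long form)

CSV/TSV, one row per (entry, source):

```
pdb_id,source,stoichiometry,symmetry,status
1z77,PISA,A2,C2,predicted
1z77,TM,A2,,predicted
1z77,SC,,,not_available
```

`source` ∈ {PDB, SC, TM, PISA, EPPIC, CONSENSUS}; `status` ∈ {predicted,
inconclusive, not_available}; empty stoichiometry/symmetry mean the
component is absent.  TM rows never carry symmetry and their stoichiometry
is order-only (A*n* = total subunit count).

## Wide benchmark table

CSV, one row per entry, read by `consensus.read_wide_table` and the
`benchmark` CLI command:

```
pdb_id,ref_stoich,ref_sym,pdb_stoich,pdb_sym,
sc_stoich,sc_sym,sc_status,tm_stoich,tm_sym,tm_status,
pisa_stoich,pisa_sym,pisa_status,eppic_stoich,eppic_sym,eppic_status
```

`ref_*` is the curated reference, `pdb_*` the deposited archive annotation.
A method's `*_status` may be left empty when it made a prediction.

## Cluster inputs

Sequences as FASTA; annotations as a TSV sidecar with header
`id<TAB>stoichiometry<TAB>symmetry`, ids matching the FASTA headers.

## Training corpus

TSV, one sentence per line: `label<TAB>sentence`, label ∈ {positive,
negative}.

## Keyword lists

One term per line, `#` comments allowed.  The oligomer list is a TSV
`keyword<TAB>subunit_count`; the evidence list is plain phrases matched
against the punctuation-stripped sentence.

## PISA assembly XML dialect

```xml
<pisa_assemblies>
  <assembly>
    <id>1</id>
    <diss_energy>7.500000</diss_energy>   <!-- kcal/mol -->
    <asa>12000.000000</asa>               <!-- A^2 -->
    <bsa>3400.000000</bsa>                <!-- A^2 -->
    <molecule>
      <chain_id>a</chain_id>
      <entity>A</entity>
      <rxx>1.000000</rxx> <rxy>0.000000</rxy> <rxz>0.000000</rxz>
      <ryx>0.000000</ryx> <ryy>1.000000</ryy> <ryz>0.000000</ryz>
      <rzx>0.000000</rzx> <rzy>0.000000</rzy> <rzz>1.000000</rzz>
      <tx>0.000000</tx> <ty>0.000000</ty> <tz>0.000000</tz>
    </molecule>
    <!-- one <molecule> per chain -->
  </assembly>
  <!-- one <assembly> per candidate oligomeric state -->
</pisa_assemblies>
```

`rxx..rzz` is the row-major 3×3 rotation, `tx,ty,tz` the translation in Å.
When `<entity>` is missing, `<chain_id>` is used as the entity label.

## EPPIC prediction XML dialect

```xml
<eppicAnalysis>
  <pdbCode>1abc</pdbCode>
  <assembly>
    <stoichiometry>A2</stoichiometry>
    <symmetry>C2</symmetry>
  </assembly>
</eppicAnalysis>
```

Either field may be absent; the stoichiometry is canonicalized on read.

## Operator TSV

Rigid operators are also accepted as 12-number rows (row-major 3×3 rotation
followed by the translation), whitespace-separated, one operator per line.
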