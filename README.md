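# macroenum

Constraint-driven combinatorial enumeration and profiling of
macrolide/macrocycle scaffold libraries.

Macrolides — macrocyclic lactones of the polyketide family — are prized
therapeutics (erythromycin, clarithromycin, azithromycin, ...) whose organic
synthesis is so demanding that candidate prioritization by virtual screening
is essential.  `macroenum` builds the virtual libraries such screening needs:
it assembles macrocycle ring scaffolds from small backbone *structural
motifs* (SMs) with two attachment points, permutes them under user-defined
structural constraints, exactly counts the resulting chemical space, and
profiles every emitted scaffold with standard drug-likeness descriptors and
MACCS-keys fingerprint similarity to probe macrolides.  It is aimed at
computational and medicinal chemists designing diversity-controlled macrolide
scaffold libraries for docking, QSAR, or chemical-space studies.

## The model

A scaffold is an ordered sequence of motifs $u_1 \dots u_L$ joined
R2$\to$R1 and closed into a ring, optionally through an ester bridge
$-\mathrm{C(=O)O}-$ (a lactone: "macrolide scaffold") or a direct bond
("macrocycle scaffold").  Motifs come in a *common* category (nine defaults:
methylene, methyl, ethyl, ketone, hydroxyl, α-hydroxy methyl, acetaldehyde
side chain, methoxy, alkene — each contributing one ring atom and at most one
oxygen) and a *rare* category for user extensions.

Eleven building rules control a run: per-category unit ranges, total ring
size range $L$ (in motif units; twelve units + ester gives a 14-membered
lactone), category priority, a permutation *skip*, the library size, ester
closure, and per-motif repeat caps.  Treating every allowed repeat of a motif
as a distinguishable unit, a pool of $n$ units taken $L$ at a time spans an
arrangement stream of exactly

$$N = \frac{n!}{(n-L)!}$$

entries, partitioned into blocks by composition (the unordered multiset of
motifs, deduplicated before permutation).  The enumerator walks this stream
with stride `skip`, so a library of $s$ scaffolds covers $s \cdot
\mathrm{skip} / N$ of the space; emitted structures are standardized and
deduplicated on canonical SMILES.  For the reference configuration (16 units,
$L=12$) the space is $16!/4! = 871{,}782{,}912{,}000$ arrangements, and one
million scaffolds at skip $10^5$ cover 11.47 % of it.

Each scaffold is profiled with MW, Wildman–Crippen SlogP, Ertl TPSA,
Lipinski-style H-bond acceptor/donor counts, rotatable bonds, heteroatom and
heavy-atom counts, plus Lipinski (MW ≤ 500, SlogP ≤ 5, HBD ≤ 5, HBA ≤ 10)
and Veber (TPSA ≤ 140 Å², NRB ≤ 10) flags.

## Worked example

```python
import macroenum as me
from macroenum.descriptors import records_to_frame
from macroenum.motifs import MotifRegistry

registry = MotifRegistry(me.default_registry().common(), shuffle_seed=1)
rules = me.v1m_rules()                       # the reference configuration
res = me.census(rules, registry)
print(f"arrangements: {res.total_arrangements:,}")   # 871,782,912,000
print(f"templates:    {res.composition_count}")      # 261
print(f"coverage:     {res.coverage:.2%}")           # 11.47%

small = me.scaled(rules, library_size=5, skip=10**10)
out = me.run_enumeration(small, registry)
print(records_to_frame(out.records)[["smiles", "MW", "TPSA", "HBA", "HBD"]].round(2))
```

which prints five twelve-unit macrolactone scaffolds sampled ten billion
stream positions apart, e.g.

```
                                                 smiles      MW    TPSA  HBA  HBD
CC=C1C(=CC)C(C)(O)C(C)(O)CCCOC(=O)C(=O)C(C)C(C)C(C)C1C  394.55   83.83    5    2
CC=C1C(=O)C(=CC)C(C)C(C)C(C)CCC(C)(O)CC(C)(O)C(=O)OC1O  396.52  104.06    6    3
...
```

Every row is a distinct canonical macrolactone obeying the repeat caps; MW,
TPSA and the H-bond counts are the drug-likeness descriptors screened against
Lipinski's and Veber's thresholds.

The same pipeline is available from the shell:

```sh
macroenum fixture --n-motifs 3 --ring-size 4 --out fx/
macroenum enumerate --rules fx/rules.yaml --motifs fx/motifs.csv --out lib/ --seed 1
macroenum census    --rules fx/rules.yaml --motifs fx/motifs.csv
macroenum profile   --in lib/RS_4.csv --out prof/
macroenum similarity --in lib/RS_4.csv --probes data/example_probes_synthetic.smi --out sim/
```

Enumeration writes one `RS_<n>.sdf` / `RS_<n>.csv` pair per ring size, a
`library_info.txt` echoing every parameter plus the shuffle seed (sufficient
to reproduce the run bit for bit), and `SM_info.csv` with motif occurrence
statistics.

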