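# follisim

Kinetic ODE models of TEK (Tie2) receptor signaling in ovarian
follicles: the **Ras/ERK/MYC** and **PI3K/AKT/mTORC1** cascades, compared
across subordinate follicles (SF), dominant follicles (DF), and dominant
follicles in the presence of repressive miRNAs (DF+miRNA).

During follicle selection, dominant follicles over-express the
angiopoietin ligand ANGPT1 and its receptor TEK while down-regulating
the antagonist ANGPT2. `follisim` asks what that expression shift does
to downstream signaling dynamics: it builds the three scenario models
from one shared mass-action reaction topology, integrates them with a
stiff solver, and compares when and how strongly each pathway readout
(ppMEK, ppERK, phospho-MYC, pAkt, pCREB, pMcl1, pmTORC1, pEIF4EBP1, ...)
peaks. It is intended for systems-biology work on folliculogenesis and,
more generally, as a compact, fully tested receptor→MAPK / receptor→PI3K
scenario-comparison harness.

Every reaction is an elementary step with the net rate

    v = kf·∏[reactants] − kr·∏[products]

(e.g. `v = K1·[ANGPT1][TEK] − Kr1·[ANGPT1–TEK]` for ligand binding), and
the system evolves as `dx/dt = N·v(x)` with `N` the stoichiometric
matrix. SF and DF share every reaction and differ only in initial
amounts; DF+miRNA adds four constant miRNA species whose repression acts
as a translational block on MYC synthesis (flux divided by
`1 + strength·[miRNA]`) and as enhanced removal of TEK.

## Worked example

```python
import follisim as fs

runs = {}
for name in ("SF", "DF", "DF_miRNA"):
    model = fs.build_scenario(fs.ScenarioSpec.for_scenario(name))
    runs[name] = fs.simulate(model, fs.SimulationSettings())  # [0, 1500] s

readouts = fs.default_readouts(model)
table = fs.compare_scenarios(runs, readouts)
for ro in ("ppMEK", "ppERK", "pMYC"):
    for sc in ("SF", "DF"):
        cell = table.get(ro, sc)
        print(f"{ro:6s} {sc}: peak {cell.peak_value:.3f} at {cell.peak_time:6.1f} s")

checks = fs.qualitative_check(table, runs, readouts)
print(sum(checks.values()), "/", len(checks), "ordering checks pass")
```

prints

```
ppMEK  SF: peak 0.374 at  340.3 s
ppMEK  DF: peak 0.825 at  275.1 s
ppERK  SF: peak 1.633 at  947.6 s
ppERK  DF: peak 1.901 at  652.0 s
pMYC   SF: peak 2.112 at  827.7 s
pMYC   DF: peak 2.008 at  754.5 s
19 / 19 ordering checks pass
```

Dominant follicles activate MEK and ERK harder and earlier (ppMEK
~275 s vs ~340 s; ppERK ~652 s vs ~948 s), while phospho-MYC is the one
readout where the subordinate follicle ends up higher and later — its
slowly accumulating MYC pool is converted late, after the dominant
follicle's early conversion product has already decayed. The ordering
checks cover all reported cross-scenario comparisons, including the
SF > DF > DF+miRNA ordering of total MYC and the near-overlap of the DF
and DF+miRNA ppMEK/ppERK curves.

The same pipeline is available from the shell:

```sh
follisim reproduce --out results/          # build → simulate → compare → plots
follisim build --out models/               # emit the three models as SBML
follisim compare --config myrun.yaml       # custom scenarios/tolerances
```

`reproduce` exits 0 iff every qualitative check passes, and writes the
comparison table (CSV), check results (JSON), per-scenario time courses,
SBML files, three-line figures (SF blue, DF black, DF+miRNA red) and the
exact configuration used.

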