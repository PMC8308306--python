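# mnsim

Scenario simulation of micronutrient interventions for women of
reproductive age. The package builds daily diets (meals → dishes →
ingredient masses), layers interventions on them — mandatory fortification
(iodized salt, vitamin A oil, multi-nutrient wheat flour), biofortification
(vitamin A maize and orange sweet potato), supplementation (iron–folic
acid, high-dose vitamin A) and micronutrient-rich food swaps — totals
per-day intake of six micronutrients (iron, zinc, vitamin A, niacin,
folate, iodine) and evaluates coverage against EAR/RNI/UL reference values,
flagging inadequacy and risk of excess.

## Layout

| module | role |
|---|---|
| `mnsim.composition` | food composition model, CSV I/O, vitamin A (IU / retinyl palmitate / β-carotene → µg RAE) and iodate → iodine conversions |
| `mnsim.diet` | dishes, meal plans, diet scenarios; flattening and daily intake totalling; food substitution; TOML scenario files |
| `mnsim.interventions` | fortification / biofortification / supplement / food-swap layers and bundle composition with per-layer contributions |
| `mnsim.adequacy` | reference-value registry (CSV-backed), %EAR/%RNI/%UL, risk classification, iodine body-weight UL rule |
| `mnsim.reporting` | coverage report rows; CSV / JSON / markdown rendering |
| `mnsim.cli` | `mnsim` command-line tool |
| `mnsim.fixtures` | calibrated Benin/Ghana cell fixtures, seeded synthetic scenarios, brute-force intake oracle |

The eight country × setting × group fixture cells are represented as one
calibrated composite basal food plus named vehicle foods (salt, oil, wheat
flour, maize porridge, snacks). Vehicle daily masses are back-calculated
from the published fortified-minus-basal intake deltas through the
package's own converters; residuals that cannot be closed from the
published programme levels are recorded in each fixture's manifest instead
of being forced to zero.

## CLI

```sh
mnsim simulate --country benin --setting urban --group npnl --bundle diet --format markdown
mnsim simulate --country ghana --setting urban --group pl \
      --bundle diet_fortification_supplementation --format json --out report.json
mnsim report --config report.json --format csv
mnsim matrix --country ghana --format csv
mnsim fixtures --out fixtures/        # emit composition.csv / scenario.toml / manifest.json per cell
```

Exit codes: 2 for usage/config-path errors, 1 for validation failures.

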