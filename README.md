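# velopace

Pacing-strategy modelling and optimization for road-cycling individual time
trials.

A course is divided into constant-grade, constant-heading segments (with
optional corner geometry). A physics model balances aerodynamic drag
(vector wind), rolling resistance and gravity to relate speed and pedal
power on each segment. Riding above the rider's *recovery power* draws on a
finite energy budget; a real-coded genetic algorithm allocates one target
speed per segment to minimize total course time while keeping the spent
budget within its limit. Corners cap speed at the friction-limited safe
speed through the widest arc that fits the intersection, and are ridden
power-free.

## Modules

| module | concern |
| --- | --- |
| `velopace.course` | segments/courses, CSV table I/O, profile segmentation, GPX ingestion, fixtures (`make_track_400m`, `make_bridge_course`, `random_course`) |
| `velopace.physics` | force breakdown, relative wind, power↔speed inversion, recovery/coasting speeds |
| `velopace.cornering` | effective turn radius `R = r + d(1 − sin(θ/2))`, safe speed `√(μ_sli·g·R)`, per-segment speed caps |
| `velopace.energy` | strategy simulation, above-recovery work ledger, constant-power budget-exhausting baseline |
| `velopace.optimizer` | the GA (tournament selection, linear recombination, Gaussian mutation, elitism, linear overspend penalty) plus a brute-force grid oracle |
| `velopace.cli` | `velopace simulate` / `velopace optimize`, YAML config, deterministic reports |

## CLI

Runs are driven by a YAML config:

```yaml
course:
  fixture: track400        # or: path: my_course.csv
rider:
  mass: 75.0               # kg, rider + equipment
  recovery_power: 300.0    # W, sustainable indefinitely
  energy_budget: 20000.0   # J available above recovery power
environment:
  surface: dry             # dry | wet (sets friction defaults)
  wind_speed: 3.0          # m/s
  wind_direction: 180.0    # degrees, direction the wind blows TOWARD
ga:
  population_size: 500
  max_generations: 200
  seed: 1
output:
  dir: out
```

```sh
velopace simulate -c config.yaml --speed 12       # fixed constant speed
velopace simulate -c config.yaml --strategy v.txt # one speed per segment
velopace optimize -c config.yaml                  # GA vs constant-power baseline
```

Reports (`segments.csv`, `summary.json`, and for optimize
`best_strategy.csv` + `history.csv`) embed the fully resolved configuration,
so any run is reconstructible from its own output. Seeded runs are
byte-identical. Exit codes: 0 ok, 1 validation error, 2 numerical error.

The default rider parameters are documented placeholders for a generic
elite rider, not measured values; override them per athlete.

## Python API sketch

```python
import velopace as vp

course = vp.make_bridge_course(mode="up_down")
rider = vp.Rider(energy_budget=15_000.0)
env = vp.Environment(wind_speed=2.0, wind_direction=180.0)

result = vp.optimize(course, rider, env, vp.GAParams(seed=1))
res = vp.simulate(result.best_strategy, course, rider, env)
print(result.best_time, res.powers)
```

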