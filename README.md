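# fuzzymotion

Fuzzy-logic motion detection for a two-module bracelet sensor worn on the
forearm. The bracelet carries two small resistive sensor modules over the
extensor carpi ulnaris and flexor carpi ulnaris; muscle contraction and
relaxation flex the skin surface, and a transducer turns the resulting
surface-resistance changes into two voltage channels sampled at 1 kHz.
`fuzzymotion` implements the signal-processing side of that system: a
Mamdani-style fuzzy inference pipeline that classifies the two-channel
signal, window by window, into four forearm motions — wrist extension (WE),
ulnar deviation (UD), finger flexion (FF), wrist flexion (WF) — plus the
resting "off" state. It is written for anyone building or studying
low-channel-count wearable gesture interfaces (an sEMG alternative), and it
ships a synthetic-signal generator so the whole pipeline can be exercised
and tested without hardware.

## The algorithm

Per channel, the mean of every 5 consecutive samples is fuzzified through a
calibrated input membership function: six triangular memberships with 50%
overlap, labeled `High_N, Low_N, Off, Low, Med, High`, with peaks at

```
(3X_N - X_O)/2,  X_N,  X_O,  (X_O + X_P)/2,  X_P,  (X_O + 3X_P)/2
```

where the anchors are measured on the wearer: `X_N` = mean negative voltage
during wrist extension, `X_O` = mean voltage at rest, `X_P` = mean positive
voltage during the other three motions. Inside the support each value
activates at most two adjacent labels with complementary weights summing to
1; beyond the outer peaks a single label saturates at weight 1.

The label pair (one per channel) is matched against a 36-entry rule base —
one rule per ordered pair of the six labels — where each rule assigns every
output state a strength `Low`, `Med` or `High` with center values
w ∈ {0.5, 1, 2}. A rule fires iff both of its label weights are nonzero,
with firing strength mᵢ = min of the two weights. Each state's crisp score
is the weighted centroid

```
x = Σᵢ mᵢ·wᵢ / Σᵢ mᵢ        (over the fired rules)
```

so every score lies in [0.5, 2], and the decided motion is the state with
the maximum score (ties keep the previous decision). Decisions are coded
1 = off, 2 = WE, 3 = UD, 4 = FF, 5 = WF on disk.

Only 18 of the 36 published rule rows are known; the shipped default table
reproduces those verbatim and fills the rest by a documented completion
(all-`Low`, plus mirroring where only one direction of a pair is
published), flagging every filled row `inferred`. The table is an ordinary
JSON/CSV config artifact and is meant to be replaced per deployment.

## Worked example

```sh
python examples/02_rules_and_inference.py
```

```
inputs: module1 = 0.4 V, module2 = 0.05 V
4 rules fire:
  rule 15 (Off, Off) m = 0.20  strengths = ('Low', 'Low', 'Low', 'Low', 'High')
  rule 16 (Off, Low) m = 0.10  strengths = ('Low', 'High', 'Low', 'Low', 'Med')
  rule 21 (Low, Off) m = 0.80  strengths = ('Low', 'High', 'Low', 'Low', 'Med')
  rule 22 (Low, Low) m = 0.10  strengths = ('Low', 'Med', 'Low', 'Low', 'Med')

defuzzification scores (each in [0.5, 2]):
  wrist_extension  0.5000
  ulnar_deviation  1.6667
  finger_flexion   0.5000
  wrist_flexion    0.5000
  off_state        1.1667

decision: ulnar_deviation
```

Module 1 sits between the `Off` and `Low` peaks (weights 0.2/0.8) and
module 2 near rest, so four rules fire; the ulnar-deviation score
(0.2·0.5 + 0.1·2 + 0.8·2 + 0.1·1)/1.2 ≈ 1.67 dominates and the window is
decided as ulnar deviation. The other examples cover fuzzification
(`01`), simulating and classifying a full 30 s sequence (`03`), the
24-sequence study with both accuracy rates (`04`), and the documented
WE→UD failure mode reproduced via the stress scenario (`05`).

The same operations are available from the shell:

```sh
fuzzymotion simulate --all-sequences --seed 7 --out seqs/
fuzzymotion classify seqs/seq_01.csv --out decisions.csv
fuzzymotion calibrate recording.csv segments.json --out calib.json
fuzzymotion evaluate --pred decisions.csv --truth seqs/seq_01.csv --out report.json
```

## Evaluation protocol

The study protocol records 24 sequences — every permutation of the four
motions, each 30 s (5 s rest, four 5 s motion plateaus, 5 s rest). Per
motion, `accuracy rate 1` is the percentage of correctly decided windows
pooled over all sequences; `accuracy rate 2` excludes sequences flagged as
containing a detection failure (≥ 1 s of contiguous misclassification
inside one plateau). Windows within 250 ms of a ground-truth change are
excluded from both, since scoring inside a movement ramp is ill-posed.

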