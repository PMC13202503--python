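# Recording format (JSON-Lines dialect)

A session recording is a single `.jsonl` file: one JSON object per line,
tagged by `type`. All positions are meters in the table frame (origin at
the table center, +x user's right, +y away from the user, +z up); all
timestamps are seconds on a per-session clock. Floats round-trip exactly
through the standard JSON encoder.

## Header (first line, required)

```json
{"type": "header", "format": "eyehand-recording", "version": 1,
 "metadata": {"seed": 1, "headset_rate_hz": 40.0, "external_rate_hz": 30.0,
              "spacing_m": 0.14}}
```

`metadata` is free-form; the simulator records its seeds and nominal rates.

## Schedule (one line)

```json
{"type": "schedule", "seed": 1, "timeout": 10.0,
 "episodes": [{"round": 1, "location_id": "s3r2", "color": "violet",
               "hand": "right", "post_stamp_delay": 1.73}, ...]}
```

Location ids are `s<sector>r<ring>` with sector 1 = leftmost, ring 1 =
innermost.

## Stream records

| tag | fields | notes |
|---|---|---|
| `gaze` | `t`, `origin` [3], `direction` [3] (unit), `hit` | headset clock, 40 Hz nominal; `hit` is the intersected object id (`"table"`, a location id, `"pad_violet"`, `"pad_orange"`) or null |
| `head` | `t`, `position` [3], `forward` [3] | headset pose, unfiltered |
| `hand` | `t`, `source` (`"headset"`/`"external"`), `valid`, `position` [3] (present only when valid), optional `t_send` | `t` is the receiver clock; external records carry the sender timestamp in `t_send` for initial clock-offset estimation |
| `body` | `t`, `joints` {name: [3]}, optional `t_send` | external tracker, 30 Hz nominal; only tracked joints appear; joint names: `chest`, `shoulder_left`, `shoulder_right`, `head`, `hand_left`, `hand_right` |
| `event` | `t`, `kind`, `episode` | `kind` in `paper_appear`, `paper_fixated`, `ink_entered`, `ink_exited`, `stamp`, `timeout_advance` |

Per-stream timestamps are strictly increasing. Every episode has a
`paper_appear` and exactly one closing `stamp` or `timeout_advance`.

Readers reject files without the header line (`FormatError`), unknown tags
(`FormatError` naming the tag), and malformed lines (`ParseError` with the
1-based line number). `read_recording(write_recording(x))` reproduces `x`
field-for-field.

## Companion outputs

Metric tables (`eyehand metrics`) are CSV with one row per episode; fused
trajectories (`eyehand process`) and ground-truth hand trajectories
(`eyehand simulate --truth-out`) are CSV with columns `t,x,y,z[,sd,valid]`.
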