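# Coral mini dev board, int8 model on CPU.
name: coral
sleep_current_mA: 240
phases:
- {name: capture_with_flash, avg_current_mA: 400, duration_s: 0.062}
- {name: inference, avg_current_mA: 460, duration_s: 0.135}
- {name: store_and_upload, avg_current_mA: 450, duration_s: 0.08}
- {name: other_functions, avg_current_mA: 240, duration_s: 62.723}
battery_capacity_mAh: 6700
cycles_per_day: 1
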