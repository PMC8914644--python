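# Raspberry Pi 4 Model B running the int8 model.
name: rpi4
sleep_current_mA: 410
phases:
- {name: capture_with_flash, avg_current_mA: 470, duration_s: 0.914}
- {name: inference, avg_current_mA: 560, duration_s: 0.174}
- {name: store_and_upload, avg_current_mA: 490, duration_s: 0.918}
- {name: other_functions, avg_current_mA: 410, duration_s: 60.994}
battery_capacity_mAh: 6700
cycles_per_day: 1
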