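# ESP32-CAM running an int8 model on a TFLite-Micro-class engine.
name: esp32
sleep_current_mA: 6
phases:
- {name: capture_with_flash, avg_current_mA: 180, duration_s: 2}
- {name: inference, avg_current_mA: 85, duration_s: 51}
- {name: store_and_upload, avg_current_mA: 150, duration_s: 3.5}
- {name: other_functions, avg_current_mA: 70, duration_s: 6.5}
battery_capacity_mAh: 6700
cycles_per_day: 1
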