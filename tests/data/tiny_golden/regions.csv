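tract_id,region_id
R00-T000,R00
R00-T001,R00
R00-T002,R00
R00-T003,R00
R00-T004,R00
R00-T005,R00
R00-T006,R00
R00-T007,R00
R00-T008,R00
R00-T009,R00
R00-T010,R00
R00-T011,R00
R01-T000,R01
R01-T001,R01
R01-T002,R01
R01-T003,R01
R01-T004,R01
R01-T005,R01
R01-T006,R01
R01-T007,R01
R01-T008,R01
R01-T009,R01
R01-T010,R01
R01-T011,R01
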