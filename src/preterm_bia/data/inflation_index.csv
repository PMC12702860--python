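year,index
2017,100.0
2018,102.0
2019,104.9
2020,109.2
2021,111.3
2022,114.9
2023,118.3
2024,121.8
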