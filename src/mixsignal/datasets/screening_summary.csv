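crop,country,emitter,receiver,mean_exposed,se_exposed,mean_control,se_control,p_value
winter_wheat,Bosnia and Herzegovina & Serbia,NS Rani otkos,NS 40S,7.37,0.17,8.63,0.15,0.0001
winter_wheat,Bosnia and Herzegovina & Serbia,NS 40S,NS Rani otkos,7.21,0.18,8.70,0.15,0.0001
winter_wheat,Bosnia and Herzegovina & Serbia,NS Rani otkos,Simonida,8.10,0.16,8.61,0.16,0.13
winter_wheat,Bosnia and Herzegovina & Serbia,Simonida,NS Rani otkos,8.60,0.17,8.70,0.15,0.97
winter_wheat,Bosnia and Herzegovina & Serbia,NS 40S,Simonida,8.15,0.17,8.61,0.16,0.20
winter_wheat,Bosnia and Herzegovina & Serbia,Simonida,NS 40S,8.22,0.15,8.63,0.15,0.35
winter_wheat,Bulgaria,Enola,Lazarka,7.75,0.14,9.10,0.11,0.0001
winter_wheat,Bulgaria,Lazarka,Enola,7.65,0.24,8.70,0.12,0.0004
winter_wheat,Bulgaria,Enola,Apolon,8.00,0.19,8.70,0.11,0.036
winter_wheat,Bulgaria,Apolon,Enola,8.05,0.15,8.70,0.12,0.056
winter_wheat,Bulgaria,Lazarka,Apolon,8.90,0.13,8.70,0.11,0.90
winter_wheat,Bulgaria,Apolon,Lazarka,8.95,0.09,9.10,0.11,0.98
winter_wheat,United Kingdom,Hereward,Xi19,7.00,0.19,8.95,0.20,0.0001
winter_wheat,United Kingdom,Xi19,Hereward,8.15,0.17,8.95,0.14,0.014
winter_wheat,United Kingdom,Claire,Hereward,7.80,0.16,8.95,0.14,0.0002
winter_wheat,United Kingdom,Hereward,Claire,7.45,0.14,9.00,0.15,0.001
winter_wheat,United Kingdom,Xi19,Claire,8.40,0.11,8.90,0.18,0.19
winter_wheat,United Kingdom,Claire,Xi19,8.15,0.25,7.80,0.33,0.84
spring_barley,Bosnia and Herzegovina,Matej,Jaran,5.00,0.39,6.60,0.42,0.021
spring_barley,Bosnia and Herzegovina,Jaran,Matej,4.30,0.41,4.30,0.42,0.99
spring_barley,Bosnia and Herzegovina,Scarlett,Jaran,5.05,0.38,6.60,0.42,0.025
spring_barley,Bosnia and Herzegovina,Jaran,Scarlett,6.10,0.31,5.80,0.48,0.96
spring_barley,Bosnia and Herzegovina,Scarlett,Matej,3.60,0.51,4.30,0.42,0.76
spring_barley,Bosnia and Herzegovina,Matej,Scarlett,5.80,0.33,5.80,0.48,0.99
spring_barley,Finland,Vertti,Toria,7.11,0.25,8.17,0.20,0.01
spring_barley,Finland,Toria,Vertti,5.44,0.22,6.61,0.32,0.01
spring_barley,Finland,Vertti,Alvari,6.39,0.29,7.17,0.31,0.25
spring_barley,Finland,Alvari,Vertti,7.22,0.17,6.61,0.32,0.42
spring_barley,Finland,Toria,Alvari,7.11,0.23,7.17,0.31,0.99
spring_barley,Finland,Alvari,Toria,7.28,0.24,8.17,0.20,0.56
spring_barley,Sweden,Fairytale,Salome,7.25,0.41,8.50,0.26,0.027
spring_barley,Sweden,Salome,Fairytale,6.75,0.37,8.05,0.28,0.023
spring_barley,Sweden,Anakin,Salome,8.00,0.37,8.50,0.26,0.59
spring_barley,Sweden,Salome,Anakin,6.70,0.45,8.35,0.18,0.018
spring_barley,Sweden,Fairytale,Anakin,7.10,0.35,8.35,0.18,0.11
spring_barley,Sweden,Anakin,Fairytale,8.06,0.36,8.05,0.28,0.89
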