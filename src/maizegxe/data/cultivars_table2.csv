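name,P1,P2,P5,G2,G3,PHINT
Sammaz 54,227.4,0.01,518.3,523.3,6.91,42.10
Sammaz 28,192.3,0.01,527.8,514.3,6.99,36.90
Ife Hybrid 5,213.7,0.01,511.6,518.7,7.09,40.00
Ife Hybrid 6,223.6,0.01,520.7,606.7,7.47,35.70
Early White,270.0,0.01,614.3,713.4,6.58,45.00
Sammaz 32,282.0,0.01,601.0,822.0,6.55,45.04
Sammaz 34,287.0,0.01,596.0,827.0,6.77,40.00
Sammaz 41,283.6,0.01,550.7,806.9,7.76,37.00
M1026-10,288.1,0.01,683.4,819.3,7.80,45.50
M1227-12,288.6,0.01,679.2,816.4,7.72,45.50
IWDC2,290.2,0.01,692.7,829.6,8.51,42.90
M0926-8,289.8,0.01,781.8,834.1,8.42,41.20
Oba Super 9,293.1,0.01,768.1,828.7,7.83,45.00
Sammaz 11,298.6,0.01,772.9,830.7,7.80,45.00
TZL-COMP4,293.7,0.01,769.2,786.7,7.59,39.98
TZBSR,294.1,0.01,789.3,846.9,7.17,45.00
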