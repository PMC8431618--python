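network,phi,q,rank_promethee,rank_vikor
AlexNet,-86.54004365,0.78423285,15,15
Vgg16,16.31877628,0.51048488,8,9
Vgg19,-63.8124359,0.74766659,13,13
Inceptionv1,-57.19966687,0.68096691,12,12
Inceptionv3,132.2050634,0.18466346,3,3
ResNet18,15.25546934,0.4614654,9,8
ResNet50,115.1633097,0.21251132,4,4
ResNet101,150.8418215,0.0,1,1
InceptionResv2,28.425464,0.4496109,7,7
Xception,-29.98203689,0.60787425,11,11
DenseNet201,133.2355605,0.07998389,2,2
MobileNetv2,72.89230795,0.42167181,6,6
ShuffleNet,-106.9819714,0.8594925,18,18
NasnetMobile,-89.20093646,0.84854,16,17
NasnetLarge,73.3193101,0.33461685,5,5
DarkNet19,-76.30565263,0.81073772,14,16
DarkNet53,1.456682009,0.56957337,10,10
EfficientNetB0,-95.9301979,0.78239429,17,14
SqueezeNet,-133.1608231,1.0,19,19
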