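network,mean_acc,std_acc,mean_sen,std_sen,mean_spe,std_spe,mean_f1,std_f1,mean_fnr,std_fnr,mean_fpr,std_fpr,mean_pre,std_pre,mean_mcc,std_mcc,mean_err,std_err
AlexNet,87.07,5.11,84.9,10.95,89.2,3.7,86.39,6.28,15.1,10.95,10.8,3.7,88.57,3.49,74.6,9.87,12.93,5.11
Vgg16,89.7,6.23,86.94,9.34,92.4,6.5,89.18,6.9,13.06,9.34,7.6,6.5,91.98,6.4,79.76,12.1,10.3,6.23
Vgg19,87.37,7.01,83.27,11.0,91.4,10.33,86.58,7.76,16.73,11.0,8.6,10.33,91.29,9.02,75.64,13.38,12.63,7.01
Inceptionv1,87.78,5.87,87.55,8.88,88.0,11.0,87.65,5.92,12.45,8.88,12.0,11.0,88.71,9.11,76.3,11.22,12.22,5.87
Inceptionv3,92.93,8.01,88.98,11.82,96.8,4.32,92.29,9.05,11.02,11.82,3.2,4.32,96.11,5.49,86.18,15.55,7.07,8.01
ResNet18,90.0,5.68,89.18,4.71,90.8,10.13,89.97,5.38,10.82,4.71,9.2,10.13,91.23,9.32,80.41,11.34,10.0,5.68
ResNet50,92.42,7.07,90.2,11.24,94.6,5.22,91.95,7.81,9.8,11.24,5.4,5.22,94.2,5.69,85.21,13.85,7.58,7.07
ResNet101,94.34,7.28,92.86,12.14,95.8,3.19,93.89,8.26,7.14,12.14,4.2,3.19,95.36,3.94,88.96,14.02,5.66,7.28
InceptionResv2,90.3,7.96,88.57,10.54,92.0,5.79,89.87,8.63,11.43,10.54,8.0,5.79,91.34,6.77,80.71,15.82,9.7,7.96
Xception,88.99,6.79,90.0,7.85,88.0,8.8,89.02,6.68,10.0,7.85,12.0,8.8,88.39,8.06,78.3,13.59,11.01,6.79
DenseNet201,93.94,4.97,93.47,3.86,94.4,8.73,93.96,4.7,6.53,3.86,5.6,8.73,94.75,7.64,88.15,9.6,6.06,4.97
MobileNetv2,90.81,7.24,85.51,11.95,96.0,3.39,89.9,8.14,14.49,11.95,4.0,3.39,95.23,4.32,82.25,13.98,9.19,7.24
ShuffleNet,86.06,6.84,80.61,9.16,91.4,14.33,85.24,6.46,19.39,9.16,8.6,14.33,91.99,11.52,73.6,13.19,13.94,6.84
NasnetMobile,86.57,6.47,80.82,12.71,92.2,5.97,85.25,7.87,19.18,12.71,7.8,5.97,91.28,5.36,74.09,12.12,13.43,6.47
NasnetLarge,91.31,7.08,88.16,7.24,94.4,7.7,90.96,7.22,11.84,7.24,5.6,7.7,94.04,7.9,82.84,14.17,8.69,7.08
DarkNet19,86.77,4.14,81.02,5.43,92.4,3.36,85.79,4.65,18.98,5.43,7.6,3.36,91.22,3.95,73.98,8.15,13.23,4.14
DarkNet53,89.19,6.15,83.88,9.88,94.4,2.97,88.26,7.22,16.12,9.88,5.6,2.97,93.42,4.0,78.87,11.79,10.81,6.15
EfficientNetB0,86.87,3.44,85.31,3.86,88.4,4.88,86.56,3.51,14.69,3.86,11.6,4.88,87.96,4.91,73.86,7.03,13.13,3.44
SqueezeNet,84.65,2.38,86.73,4.95,82.6,6.19,84.83,2.31,13.27,4.95,17.4,6.19,83.34,4.8,69.66,4.75,15.35,2.38
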